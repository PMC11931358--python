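"""Counting-process primitives: Kaplan–Meier, Nelson–Aalen, step curves.

Conventions
-----------
* Ties: events at a time ``t`` are counted against the at-risk set
  ``{i : X_i >= t}``, which includes subjects censored at exactly ``t``
  (events happen first).  The reverse Kaplan–Meier estimate of the
  censoring distribution uses the complementary convention: a subject
  with an event at ``t`` is not at risk for censoring at ``t``.
* At-risk fractions ``Ȳ_z(t)`` are normalized by the *total* sample size
  ``n``, not the arm size, so arm-level variance terms already carry the
  allocation fraction.
* Curves are right-continuous step functions; tail integrals
  ``∫_t^τ S(u) du`` are exact segment sums, never quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepSurvivalCurve",
    "CumHazardCurve",
    "CountingFrame",
    "ArmComponents",
    "counting_frame",
    "km_curve",
    "reverse_km_curve",
    "nelson_aalen",
    "arm_components",
    "step_tail_integrals",
]


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Right-continuous survival step function starting at 1.

    ``values[k]`` is the curve's value on ``[jump_times[k], jump_times[k+1])``;
    before the first jump the value is 1.  ``max_followup`` is the largest
    observed time in the data the curve was fitted to (evaluation beyond it
    extends the last value flat).
    """

    jump_times: np.ndarray
    values: np.ndarray
    max_followup: float

    def __post_init__(self):
        object.__setattr__(self, "jump_times", np.asarray(self.jump_times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.jump_times.shape != self.values.shape:
            raise ValueError("jump_times and values must align")
        if self.jump_times.size and np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if self.values.size and (
            np.any(np.diff(self.values) > 1e-12)
            or self.values[0] > 1 + 1e-12
            or self.values[-1] < -1e-12
        ):
            raise ValueError("values must be nonincreasing within [0, 1]")

    def _eval(self, t, side: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.jump_times, t, side=side) - 1
        return np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)

    def survival(self, t):
        """S(t), right-continuous."""
        out = self._eval(t, "right")
        return out if np.ndim(t) else float(out)

    def left_limit(self, t):
        """S(t-)."""
        out = self._eval(t, "left")
        return out if np.ndim(t) else float(out)

    __call__ = survival

    def tail_integral(self, t: float, tau: float) -> float:
        """Exact ``∫_t^τ S(u) du`` over the step segments."""
        if t > tau:
            raise ValueError("t must not exceed tau")
        ts = self.jump_times
        i0 = np.searchsorted(ts, t, side="right")
        i1 = np.searchsorted(ts, tau, side="right")
        pts = np.concatenate(([t], ts[i0:i1], [tau]))
        vals = np.concatenate(([self.survival(t)], self.values[i0:i1]))
        return float(np.sum(np.diff(pts) * vals))


@dataclass(frozen=True)
class CumHazardCurve:
    """Nelson–Aalen cumulative hazard: jumps ``increments`` at ``times``."""

    times: np.ndarray
    increments: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def value(self, t) -> np.ndarray:
        cum = np.concatenate(([0.0], self.cumulative))
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        out = cum[idx]
        return out if np.ndim(t) else float(out)

    __call__ = value


@dataclass(frozen=True)
class CountingFrame:
    """Distinct event times with event and at-risk counts for one group.

    ``n_total`` is the normalizer for the at-risk fraction (the full trial
    size for an arm of a two-arm dataset, the group size for a standalone
    sample).
    """

    event_times: np.ndarray
    n_events: np.ndarray
    n_at_risk: np.ndarray
    n_total: int

    @property
    def at_risk_fraction(self) -> np.ndarray:
        """Ȳ(t) at the event times, normalized by ``n_total``."""
        return self.n_at_risk / self.n_total

    @property
    def hazard_increments(self) -> np.ndarray:
        """dΛ̂(t) = d(t) / {n Ȳ(t)} at the event times."""
        return self.n_events / self.n_at_risk

    def martingale_increments(self, time, event) -> np.ndarray:
        """Dense per-subject table dM̂_i(t_k); columns sum to zero.

        Intended for diagnostics and small samples (O(n·K) memory); the
        score computations in :func:`arm_components` never materialize it.
        """
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        dN = (time[:, None] == self.event_times) & (event[:, None] == 1)
        at_risk = time[:, None] >= self.event_times
        return dN.astype(float) - at_risk * self.hazard_increments


def counting_frame(time, event, n_total: int | None = None) -> CountingFrame:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no subjects in arm")
    et = np.unique(time[event == 1])
    # at risk: X_i >= t (censored at t still at risk — events first)
    order = np.sort(time)
    n_at_risk = time.size - np.searchsorted(order, et, side="left")
    if et.size:
        idx = np.searchsorted(et, time[event == 1])
        d = np.bincount(idx, minlength=et.size).astype(float)
    else:
        d = np.empty(0)
    return CountingFrame(et, d, n_at_risk.astype(float), int(n_total or time.size))


def km_curve(time, event) -> StepSurvivalCurve:
    """Kaplan–Meier product-limit estimate for one group."""
    cf = counting_frame(time, event)
    surv = np.cumprod(1.0 - cf.n_events / cf.n_at_risk)
    return StepSurvivalCurve(cf.event_times, surv, float(np.max(time)))


def reverse_km_curve(time, event) -> StepSurvivalCurve:
    """Censoring-distribution estimate Ĝ (censoring as the event).

    At tied times events precede censorings, so the at-risk set for a
    censoring at ``t`` excludes subjects with an event at ``t``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    ct = np.unique(time[event == 0])
    if ct.size == 0:
        return StepSurvivalCurve(np.empty(0), np.empty(0), float(np.max(time)))
    order = np.sort(time)
    n_at_risk = time.size - np.searchsorted(order, ct, side="left")
    idx = np.searchsorted(ct, time[event == 0])
    dc = np.bincount(idx, minlength=ct.size).astype(float)
    idx_e = np.searchsorted(ct, time[event == 1])
    in_range = (idx_e < ct.size) & (ct[np.clip(idx_e, 0, ct.size - 1)] == time[event == 1])
    de = np.bincount(idx_e[in_range], minlength=ct.size).astype(float)
    denom = n_at_risk - de
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(denom > 0, 1.0 - dc / denom, 0.0)
    surv = np.cumprod(factors)
    return StepSurvivalCurve(ct, surv, float(np.max(time)))


def nelson_aalen(time, event, n_total: int | None = None) -> CumHazardCurve:
    cf = counting_frame(time, event, n_total)
    return CumHazardCurve(cf.event_times, cf.hazard_increments)


@dataclass(frozen=True)
class ArmComponents:
    """Everything the RMST machinery needs from one group's data.

    Attributes
    ----------
    event_times, hazard_increments, at_risk_fraction :
        Restricted to event times within ``[0, τ]``.
    w :
        Tail integrals ``∫_{t_k}^τ Ŝ(u) du`` of the group's Kaplan–Meier
        curve at each retained event time.
    theta :
        ``∫_0^τ Ŝ(u) du``, the group RMST estimate.
    var_term :
        ``Σ_k w_k² / Ȳ(t_k) · dΛ̂(t_k)``, this group's contribution to the
        plug-in variance of the √n-scaled estimator.
    subject_integrals :
        ``I_i = ∫_0^τ {∫_t^τ Ŝ du / Ȳ(t)} dM̂_i(t)`` for each subject of
        the group, in input order.
    """

    event_times: np.ndarray
    hazard_increments: np.ndarray
    at_risk_fraction: np.ndarray
    w: np.ndarray
    theta: float
    var_term: float
    subject_integrals: np.ndarray
    max_followup: float


def arm_components(time, event, tau: float, n_total: int | None = None,
                   extend: str = "flat") -> ArmComponents:
    """Fit KM/Nelson–Aalen for one group and assemble score components.

    ``extend`` controls behaviour when the group's largest observed time
    falls short of ``tau``: ``"flat"`` carries the last Kaplan–Meier value
    forward with a warning, ``"strict"`` raises.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no subjects in arm")
    n_total = int(n_total or time.size)
    max_fu = float(np.max(time))
    if max_fu < tau:
        msg = (f"largest observed time {max_fu:g} < tau {tau:g}; "
               "Kaplan-Meier curve extended flat beyond the data")
        if extend == "strict":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    cf = counting_frame(time, event, n_total)
    keep = cf.event_times <= tau
    et = cf.event_times[keep]
    K = et.size
    if K == 0:
        # no events within the window: Ŝ ≡ 1 on [0, τ]
        return ArmComponents(et, np.empty(0), np.empty(0), np.empty(0),
                             float(tau), 0.0, np.zeros(time.size), max_fu)
    d = cf.n_events[keep]
    Y = cf.n_at_risk[keep]
    dL = d / Y
    ybar = Y / n_total
    surv = np.cumprod(1.0 - dL)  # Ŝ at [e_k, e_{k+1})

    # tail integrals w_k = ∫_{e_k}^τ Ŝ du by reverse accumulation
    seg_end = np.concatenate((et[1:], [tau]))
    seg = surv * (seg_end - et)
    w = np.cumsum(seg[::-1])[::-1]
    theta = float(et[0] + w[0])  # Ŝ ≡ 1 on [0, e_1)

    var_term = float(np.sum(w**2 / ybar * dL))

    # per-subject ∫ f dM̂ with f_k = w_k / Ȳ(t_k):
    #   event part: f at the subject's own event time (if within [0, τ]);
    #   compensator part: Σ_{k: e_k <= X_i} f_k dΛ_k.
    f = w / ybar
    A = np.cumsum(f * dL)
    pos = np.searchsorted(et, time, side="right") - 1
    comp = np.where(pos >= 0, A[np.clip(pos, 0, None)], 0.0)
    term1 = np.zeros(time.size)
    is_ev = (event == 1) & (time <= tau)
    j = np.searchsorted(et, time[is_ev])
    term1[is_ev] = f[j]
    I = term1 - comp
    return ArmComponents(et, dL, ybar, w, theta, var_term, I, max_fu)


def step_tail_integrals(curve: StepSurvivalCurve, ts, tau: float) -> np.ndarray:
    """Vectorized ``∫_{t}^{τ} S(u) du`` for an array of lower limits."""
    ts = np.asarray(ts, dtype=float)
    knots = curve.jump_times
    i1 = np.searchsorted(knots, tau, side="right")
    kt = knots[:i1]
    vals = curve.values[:i1]
    # suffix integral from each knot to tau
    if kt.size:
        seg_end = np.concatenate((kt[1:], [tau]))
        seg = vals * (seg_end - kt)
        suffix = np.cumsum(seg[::-1])[::-1]
    else:
        suffix = np.empty(0)
    if kt.size == 0:
        return np.clip(tau - ts, 0.0, None)
    idx = np.searchsorted(kt, ts, side="right") - 1
    out = np.empty(ts.shape)
    inside = idx >= 0
    j = np.clip(idx, 0, None)
    # ∫_t^τ = (suffix from the covering knot) minus the part [kt_j, t)
    out[inside] = suffix[j][inside] - vals[j][inside] * (ts[inside] - kt[j][inside])
    # t before the first jump: S ≡ 1 on [t, kt_0)
    out[~inside] = kt[0] - ts[~inside] + suffix[0]
    return np.clip(out, 0.0, None)
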