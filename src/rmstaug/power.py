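"""Local power and design-stage sample-size machinery.

Under a local (1/√n) alternative with a common censoring law ``G`` the
variance of the √n-scaled RMST-difference estimator reduces to

    σ̃₁² = {π(1−π)}⁻¹ ∫_0^τ {∫_t^τ S₀(u) du}² / {S₀(t) G(t)} dΛ₀(t),

which depends only on the control survival curve ``S₀`` and ``G``.  The
augmented test removes ``Q₂ = π(1−π) e²`` from it, where ``e²`` is the
variance explained by projecting the martingale-residual integrals onto
the covariates — estimable from control-only (or blinded pooled)
reference data.  Two-sided power at an RMST-difference alternative
``θ_alt`` is then

    Φ(z_{α/2} − θ_alt/v) + 1 − Φ(z_{1−α/2} − θ_alt/v),

with ``v² = σ̃₁²/n`` (standard) or ``(σ̃₁² − π(1−π) e²)/n`` (augmented).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .curves import (CumHazardCurve, StepSurvivalCurve, arm_components,
                     km_curve, nelson_aalen, reverse_km_curve,
                     step_tail_integrals)
from .dataset import SurvivalDataset

__all__ = [
    "DistributionSpec", "ExponentialSpec", "PiecewiseExponentialSpec",
    "UniformSpec", "KMCurveSpec", "spec_from_config",
    "DesignSpec", "PowerResult",
    "exp_rate_from_survival", "sigma_tilde_sq", "e_squared",
    "predicted_power", "required_n", "stepwise_select",
    "reference_design_inputs",
]


# ---------------------------------------------------------------------------
# survival / censoring distribution specifications
# ---------------------------------------------------------------------------

class DistributionSpec:
    """Base for parametric or nonparametric survival-law specifications."""

    parametric = True

    def survival(self, t):
        raise NotImplementedError

    def hazard(self, t):
        raise NotImplementedError

    def tail_integral(self, t, tau):
        """∫_t^τ S(u) du; closed form where available."""
        raise NotImplementedError


@dataclass(frozen=True)
class ExponentialSpec(DistributionSpec):
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def survival(self, t):
        return np.exp(-self.rate * np.asarray(t, dtype=float))

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def tail_integral(self, t, tau):
        t = np.asarray(t, dtype=float)
        return (np.exp(-self.rate * t) - np.exp(-self.rate * tau)) / self.rate


@dataclass(frozen=True)
class PiecewiseExponentialSpec(DistributionSpec):
    """Hazard ``rates[j]`` on ``[cutpoints[j-1], cutpoints[j])`` (open-ended last)."""

    rates: tuple
    cutpoints: tuple

    def __post_init__(self):
        rates = tuple(float(r) for r in self.rates)
        cuts = tuple(float(c) for c in self.cutpoints)
        if len(rates) != len(cuts) + 1:
            raise ValueError("need one more rate than cutpoints")
        if any(r <= 0 for r in rates):
            raise ValueError("rates must be positive")
        if any(b <= a for a, b in zip(cuts, cuts[1:])) or (cuts and cuts[0] <= 0):
            raise ValueError("cutpoints must be positive and increasing")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "cutpoints", cuts)

    def _knots(self):
        return np.concatenate(([0.0], self.cutpoints))

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        knots = self._knots()
        rates = np.asarray(self.rates)
        out = np.zeros_like(t)
        for j, k in enumerate(knots):
            upper = self.cutpoints[j] if j < len(self.cutpoints) else np.inf
            out += rates[j] * np.clip(np.minimum(t, upper) - k, 0.0, None)
        return out

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(self.cutpoints), t, side="right")
        return np.asarray(self.rates)[idx]

    def tail_integral(self, t, tau):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        knots = self._knots()
        rates = np.asarray(self.rates)
        out = np.zeros_like(t)
        for j, k in enumerate(knots):
            upper = self.cutpoints[j] if j < len(self.cutpoints) else np.inf
            lo = np.clip(t, k, min(upper, tau))
            hi = np.full_like(t, min(upper, tau))
            seg = np.clip(hi - lo, 0.0, None)
            s_lo = self.survival(lo)
            out += np.where(seg > 0, s_lo * (1 - np.exp(-rates[j] * seg)) / rates[j], 0.0)
        return out if out.size > 1 else float(out[0])


@dataclass(frozen=True)
class UniformSpec(DistributionSpec):
    """Uniform(0, upper); the usual administrative-censoring law."""

    upper: float

    def __post_init__(self):
        if self.upper <= 0:
            raise ValueError("upper must be positive")

    def survival(self, t):
        return np.clip(1.0 - np.asarray(t, dtype=float) / self.upper, 0.0, 1.0)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(t < self.upper, 1.0 / (self.upper - t), np.inf)

    def tail_integral(self, t, tau):
        b = min(tau, self.upper)
        a = np.minimum(np.clip(np.asarray(t, dtype=float), 0.0, self.upper), b)
        return (b - a) - (b**2 - a**2) / (2 * self.upper)


@dataclass(frozen=True)
class KMCurveSpec(DistributionSpec):
    """Nonparametric law: a fitted step curve plus (for the event law) its
    Nelson–Aalen increments."""

    curve: StepSurvivalCurve
    cumhaz: CumHazardCurve | None = None
    parametric = False

    def survival(self, t):
        return self.curve.survival(t)

    def left_limit(self, t):
        return self.curve.left_limit(t)

    def tail_integral(self, t, tau):
        return step_tail_integrals(self.curve, np.atleast_1d(t), tau)

    @classmethod
    def from_data(cls, time, event) -> "KMCurveSpec":
        return cls(km_curve(time, event), nelson_aalen(time, event))

    @classmethod
    def censoring_from_data(cls, time, event) -> "KMCurveSpec":
        return cls(reverse_km_curve(time, event))


def spec_from_config(cfg: dict) -> DistributionSpec:
    """Build a spec from a plain config mapping.

    Supported forms::

        {kind: exponential, rate: 3.58e-4}
        {kind: exponential, survival: 0.52, at: 1825}
        {kind: piecewise_exponential, rates: [...], cutpoints: [...]}
        {kind: uniform, upper: 8}
    """
    kind = cfg.get("kind")
    if kind == "exponential":
        if "rate" in cfg:
            return ExponentialSpec(float(cfg["rate"]))
        return ExponentialSpec(exp_rate_from_survival(float(cfg["survival"]),
                                                      float(cfg["at"])))
    if kind == "piecewise_exponential":
        return PiecewiseExponentialSpec(tuple(cfg["rates"]), tuple(cfg.get("cutpoints", ())))
    if kind == "uniform":
        return UniformSpec(float(cfg["upper"]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def exp_rate_from_survival(p: float, t: float) -> float:
    """Exponential rate matching S(t) = p: ``λ = −ln(p)/t``."""
    if not 0 < p < 1:
        raise ValueError("survival probability must be in (0, 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    return -float(np.log(p)) / t


# ---------------------------------------------------------------------------
# σ̃₁², e², power, sample size
# ---------------------------------------------------------------------------

def sigma_tilde_sq(s0: DistributionSpec, g: DistributionSpec, tau: float,
                   pi: float = 0.5) -> float:
    """Null-approximated variance of √n(θ̂ − θ) from S₀ and G.

    Exact step sums for Kaplan–Meier inputs (left limits of S₀ and G at
    the event times); adaptive quadrature (relative tolerance 1e−8) for
    parametric laws.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    if isinstance(s0, KMCurveSpec):
        if s0.cumhaz is None:
            raise ValueError("km_curve spec for S0 needs hazard increments")
        keep = s0.cumhaz.times <= tau
        et = s0.cumhaz.times[keep]
        if et.size == 0:
            warnings.warn("no event mass on [0, tau]; sigma_tilde_sq = 0",
                          stacklevel=2)
            return 0.0
        dL = s0.cumhaz.increments[keep]
        w = step_tail_integrals(s0.curve, et, tau)
        s_left = s0.curve.left_limit(et)
        g_left = g.left_limit(et) if isinstance(g, KMCurveSpec) else g.survival(et)
        denom = s_left * g_left
        if np.any(denom <= 0):
            raise ValueError("S0(t-) G(t-) vanishes at an event time before tau")
        return float(np.sum(w**2 / denom * dL) / (pi * (1 - pi)))

    def integrand(t):
        w = s0.tail_integral(t, tau)
        return w**2 * s0.hazard(t) / (s0.survival(t) * g.survival(t))

    pts = sorted({float(c) for c in getattr(s0, "cutpoints", ())
                  if 0 < c < tau}
                 | ({g.upper} if isinstance(g, UniformSpec) and g.upper < tau else set()))
    val, _ = integrate.quad(integrand, 0.0, tau, points=pts or None,
                            epsrel=1e-8, limit=200)
    if val == 0.0:
        warnings.warn("no event mass on [0, tau]; sigma_tilde_sq = 0", stacklevel=2)
    return float(val / (pi * (1 - pi)))


def e_squared(reference: SurvivalDataset, tau: float, pooled: bool = False,
              pi: float = 0.5) -> float:
    """Covariate-explained variance ê² from a single-group sample.

    ``ê² = aᵀ B⁻¹ a / {n⁺ π²(1−π)²}`` with ``a = Σ g_i V_i``,
    ``B = Σ V_i V_iᵀ`` and ``g_i`` the martingale-residual integral
    ``∫_0^τ {∫_t^τ Ŝ₀ du / Ȳ₀(t)} dM̂₀,i(t)`` of subject ``i`` under the
    sample's own Kaplan–Meier / Nelson–Aalen fit.  The normalization is
    chosen so that ``Q₂ = π(1−π) e²`` is the asymptotic variance removed
    by the optimal augmentation (the trial-level influence scores carry
    ``1/π_z`` relative to the single-group scores, which contributes the
    ``{π(1−π)}⁻²``).  The reference data must be control-only; pass
    ``pooled=True`` for a blinded pooled snapshot.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    if reference.n_covariates < 1:
        raise ValueError("e_squared requires at least one covariate")
    if not pooled:
        if reference.arm is not None and np.any(reference.arm != 0):
            raise ValueError("reference data must contain only control subjects "
                             "(or pass pooled=True for blinded pooled data)")
    n_plus = reference.n
    if n_plus < reference.n_covariates + 2:
        raise ValueError("too few subjects for the covariate count")
    comp = arm_components(reference.time, reference.event, tau, n_total=n_plus)
    g = comp.subject_integrals
    V = reference.covariates
    B = V.T @ V
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError("collinear covariates in reference data")
    a = V.T @ g
    return float(a @ np.linalg.solve(B, a) / n_plus / (pi * (1 - pi)) ** 2)


@dataclass
class PowerResult:
    """Predicted local power for the standard and augmented tests."""

    sigma_tilde_sq: float
    e_sq: float
    n: int
    tau: float
    alpha: float
    pi: float
    theta_alt: float
    q2: float
    v_sq: float
    v_aug_sq: float
    power_standard: float
    power_augmented: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "sigma_tilde_sq", "e_sq", "n", "tau", "alpha", "pi", "theta_alt",
            "q2", "v_sq", "v_aug_sq", "power_standard", "power_augmented")}


def _two_sided_power(theta_alt: float, v: np.ndarray, alpha: float) -> np.ndarray:
    za = stats.norm.ppf(alpha / 2.0)  # lower-tail quantile (negative)
    shift = theta_alt / v
    return stats.norm.cdf(za - shift) + stats.norm.sf(-za - shift)


def predicted_power(theta_alt: float, n, sigma_tilde_sq: float,
                    e_sq: float = 0.0, alpha: float = 0.05,
                    pi: float = 0.5, tau: float = float("nan")):
    """Local power of the standard and augmented two-sided tests.

    ``n`` may be an array, in which case a pair of power arrays is
    returned instead of a :class:`PowerResult`.
    """
    if e_sq < 0:
        raise ValueError("e_sq must be nonnegative")
    if e_sq > 0 and abs(pi - 0.5) > 1e-12:
        raise ValueError("augmented power formula requires pi = 1/2")
    q2 = pi * (1 - pi) * e_sq
    if q2 >= sigma_tilde_sq:
        raise ValueError("augmentation variance exceeds total "
                         f"(pi(1-pi)*e_sq = {q2:g} >= sigma_tilde_sq = "
                         f"{sigma_tilde_sq:g})")
    n_arr = np.asarray(n, dtype=float)
    v = np.sqrt(sigma_tilde_sq / n_arr)
    v_aug = np.sqrt((sigma_tilde_sq - q2) / n_arr)
    p_std = _two_sided_power(theta_alt, v, alpha)
    p_aug = _two_sided_power(theta_alt, v_aug, alpha)
    if n_arr.ndim:
        return p_std, p_aug
    return PowerResult(
        sigma_tilde_sq=sigma_tilde_sq, e_sq=e_sq, n=int(n), tau=tau,
        alpha=alpha, pi=pi, theta_alt=theta_alt, q2=q2,
        v_sq=sigma_tilde_sq / float(n),
        v_aug_sq=(sigma_tilde_sq - q2) / float(n),
        power_standard=float(p_std), power_augmented=float(p_aug))


@dataclass
class DesignSpec:
    """Design parameters for sizing and re-estimation."""

    tau: float
    theta_alt: float
    alpha: float = 0.05
    target_power: float = 0.8
    pi: float = 0.5
    n_step: int = 10
    n_min: int = 10
    n_max: int = 10000

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.alpha < self.target_power < 1:
            raise ValueError("target_power must be in (alpha, 1)")
        if self.theta_alt == 0:
            raise ValueError("theta_alt must be nonzero for sizing")
        if self.n_step < 1 or self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError("invalid n grid")


def required_n(design: DesignSpec, sigma_tilde_sq: float, e_sq: float = 0.0,
               augmented: bool = False) -> int:
    """Smallest grid n with predicted power ≥ the target power."""
    grid = np.arange(design.n_min, design.n_max + 1, design.n_step)
    p_std, p_aug = predicted_power(design.theta_alt, grid, sigma_tilde_sq,
                                   e_sq if augmented else 0.0,
                                   design.alpha, design.pi)
    powers = p_aug if augmented else p_std
    hit = np.nonzero(powers >= design.target_power)[0]
    if hit.size == 0:
        raise ValueError(
            f"target power {design.target_power} not reached by n_max="
            f"{design.n_max} (power there: {powers[-1]:.4f})")
    return int(grid[hit[0]])


def stepwise_select(reference: SurvivalDataset, tau: float,
                    candidates: list[str] | None = None) -> list[tuple[str, float]]:
    """Greedy forward covariate selection by gain in ê².

    Returns the full path ``[(name, ê² with the set so far), ...]``; the
    caller decides where the gain saturates.  Candidates that make the
    Gram matrix collinear are skipped with a warning.
    """
    if candidates is None:
        candidates = list(reference.covariate_names)
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    chosen: list[str] = []
    path: list[tuple[str, float]] = []
    remaining = list(candidates)
    best_so_far = 0.0
    while remaining:
        best = None
        for cand in remaining:
            try:
                val = e_squared(reference.select_covariates(chosen + [cand]), tau)
            except np.linalg.LinAlgError:
                continue
            if best is None or val > best[1]:
                best = (cand, val)
        if best is None:
            for cand in remaining:
                warnings.warn(f"skipping collinear candidate {cand!r}", stacklevel=2)
            break
        chosen.append(best[0])
        remaining.remove(best[0])
        best_so_far = max(best_so_far, best[1])
        path.append(best)
    return path


def sigma_tilde_residual(time, event, tau: float, pi: float = 0.5) -> float:
    """Score-form estimate of σ̃₁² from a single-group sample.

    The mean squared martingale-residual integral ``n⁻¹ Σ g_i²`` divided
    by ``π(1−π)``.  Asymptotically equivalent to plugging the group's
    Kaplan–Meier curves into the integral form, and the natural companion
    of the score-form test variance.
    """
    comp = arm_components(np.asarray(time, dtype=float), np.asarray(event),
                          tau)
    return float(np.mean(comp.subject_integrals**2) / (pi * (1 - pi)))


def reference_design_inputs(reference: SurvivalDataset, tau: float,
                            pi: float = 0.5,
                            g: DistributionSpec | None = None,
                            covariates: list[str] | None = None,
                            pooled: bool = False,
                            variance_form: str = "residual") -> dict:
    """Estimate (σ̃₁², ê²) from reference (or blinded pooled) data.

    σ̃₁² defaults to the score form (:func:`sigma_tilde_residual`), which
    absorbs the empirical censoring distribution through the at-risk
    process.  Supplying a known censoring law ``g``, or requesting
    ``variance_form="plugin"``, switches to the integral form with the
    Kaplan–Meier ``S₀`` (and reverse Kaplan–Meier ``G`` unless given).
    ``ê²`` is computed when covariates are present.
    """
    s0 = KMCurveSpec.from_data(reference.time, reference.event)
    g_spec = g if g is not None else KMCurveSpec.censoring_from_data(
        reference.time, reference.event)
    if variance_form == "residual" and g is None:
        st2 = sigma_tilde_residual(reference.time, reference.event, tau, pi)
    elif variance_form in ("residual", "plugin"):
        st2 = sigma_tilde_sq(s0, g_spec, tau, pi)
    else:
        raise ValueError("variance_form must be 'residual' or 'plugin'")
    ref = reference.select_covariates(covariates) if covariates else reference
    e2 = e_squared(ref, tau, pooled=pooled, pi=pi) if ref.n_covariates else 0.0
    return {"s0": s0, "g": g_spec, "sigma_tilde_sq": st2, "e_sq": e2}
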