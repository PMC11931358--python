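"""Synthetic trial generators and the operating-characteristics study.

Six scenarios are built from a common template.  Failure times are
exponential with rate ``λ₀ = −ln(0.2)/5`` in the control arm (5-year
survival 0.2); the treatment arm is exponential with hazard ratio 1
(scenario family 1, the null), hazard ratio 0.7 (family 2, proportional
hazards), or piecewise exponential with hazard ``λ₀`` before ``t = 1``
and a reduced rate ``λ₂`` afterwards, solved so that the true RMST
difference over ``[0, 5]`` equals the family-2 value 0.514 (family 3,
non-proportional hazards).

Dependence between the failure time and two continuous baseline
covariates ``V₁ = b₁ + ε₁`` and ``V₂ = b₂ + ε₂`` (all latent terms
standard normal) is induced through a Gaussian copula: the uniform
driver of the failure time is ``U = Φ₃(b₁ + b₂ + ε)`` in setting "a"
(covariates prognostic) or ``U = Φ₁(ε)`` in setting "b" (covariates pure
noise).  Censoring is Uniform(0, 8), independent of everything;
allocation is 1:1.

Reference data are control-law draws; the "mis-matched" variant
rejection-samples subjects with ``V₁ < 1`` and ``V₂ < 1`` to emulate a
reference population that misrepresents the covariate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blinded import reestimate_n
from .dataset import SurvivalDataset
from .estimators import augmented_test, standard_test
from .power import (DesignSpec, ExponentialSpec, PiecewiseExponentialSpec,
                    UniformSpec, predicted_power, reference_design_inputs)

__all__ = [
    "SimScenario", "scenario", "SCENARIO_IDS",
    "generate_trial", "generate_reference", "true_rmst_diff", "solve_lambda2",
    "simulate_rejection_rates", "simulate_predicted_power", "simulate_ssr",
    "run_study",
]

LAMBDA0 = float(np.log(5.0) / 5.0)  # 5-year survival 0.2
SCENARIO_IDS = ("1a", "1b", "2a", "2b", "3a", "3b")


@dataclass(frozen=True)
class SimScenario:
    id: str
    copula: str                  # "a": T linked to (V1, V2); "b": independent
    family: int                  # 1 null, 2 PH, 3 non-PH
    lambda0: float = LAMBDA0
    hazard_ratio: float = 1.0    # families 1 and 2
    lambda2: float | None = None  # family 3 post-change treatment rate
    change_time: float = 1.0
    tau: float = 5.0
    censor_upper: float = 8.0
    pi: float = 0.5


def _rmst_exponential(rate: float, tau: float) -> float:
    return (1.0 - np.exp(-rate * tau)) / rate


def _rmst_piecewise(lambda0: float, lambda2: float, change: float, tau: float) -> float:
    head = (1.0 - np.exp(-lambda0 * change)) / lambda0
    tail = np.exp(-lambda0 * change) * (1.0 - np.exp(-lambda2 * (tau - change))) / lambda2
    return head + tail


def solve_lambda2(lambda0: float, change_time: float, tau: float,
                  target_diff: float) -> float:
    """Post-change treatment hazard giving the requested RMST difference.

    Solves ``RMST_pw(λ₂) − RMST_exp(λ₀) = target`` by bracketed root
    finding on the closed-form piecewise-exponential RMST; result is
    accurate to 1e−12 in the hazard and plugs back to the target
    difference within 1e−10.
    """
    base = _rmst_exponential(lambda0, tau)
    target = base + target_diff
    max_attain = (1.0 - np.exp(-lambda0 * change_time)) / lambda0 \
        + np.exp(-lambda0 * change_time) * (tau - change_time)
    if not base - 1e-12 <= target <= max_attain - 1e-12 or target_diff < 0:
        raise ValueError(
            f"target difference {target_diff:g} outside the feasible range "
            f"[0, {max_attain - base:g}) for this hazard reduction")
    if target_diff == 0:
        return lambda0

    def gap(lam2):
        return _rmst_piecewise(lambda0, lam2, change_time, tau) - target

    return float(optimize.brentq(gap, 1e-12, lambda0, xtol=1e-14, rtol=1e-12))


def true_rmst_diff(sc: SimScenario) -> float:
    """Closed-form population RMST difference of a scenario."""
    theta0 = _rmst_exponential(sc.lambda0, sc.tau)
    if sc.family == 1:
        return 0.0
    if sc.family == 2:
        return _rmst_exponential(sc.hazard_ratio * sc.lambda0, sc.tau) - theta0
    return _rmst_piecewise(sc.lambda0, sc.lambda2, sc.change_time, sc.tau) - theta0


def scenario(scenario_id: str) -> SimScenario:
    """Resolve one of the study scenarios 1a/1b/2a/2b/3a/3b."""
    sid = str(scenario_id).lower()
    if sid not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {scenario_id!r}; "
                         f"choose one of {SCENARIO_IDS}")
    family = int(sid[0])
    copula = sid[1]
    sc = SimScenario(id=sid, copula=copula, family=family,
                     hazard_ratio=0.7 if family == 2 else 1.0)
    if family == 3:
        target = true_rmst_diff(scenario("2" + copula))
        sc = replace(sc, lambda2=solve_lambda2(sc.lambda0, sc.change_time,
                                               sc.tau, target))
    return sc


def treatment_spec(sc: SimScenario):
    """Parametric law of the treatment arm."""
    if sc.family == 3:
        return PiecewiseExponentialSpec((sc.lambda0, sc.lambda2), (sc.change_time,))
    return ExponentialSpec(sc.hazard_ratio * sc.lambda0)


def control_spec(sc: SimScenario) -> ExponentialSpec:
    return ExponentialSpec(sc.lambda0)


def censoring_spec(sc: SimScenario) -> UniformSpec:
    return UniformSpec(sc.censor_upper)


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

def _draw_latents(sc: SimScenario, n: int, rng: np.random.Generator):
    b1, b2, eps1, eps2, eps = rng.standard_normal((5, n))
    V = np.column_stack((b1 + eps1, b2 + eps2))
    if sc.copula == "a":
        U = stats.norm.cdf((b1 + b2 + eps) / np.sqrt(3.0))
    else:
        U = stats.norm.cdf(eps)
    return V, U


def _failure_from_uniform(sc: SimScenario, U: np.ndarray, treated: np.ndarray):
    """Push the uniform driver through each arm's inverse CDF."""
    E = -np.log(np.clip(U, 1e-300, None))  # unit exponential
    T = E / sc.lambda0
    if sc.family == 2:
        T = np.where(treated, E / (sc.hazard_ratio * sc.lambda0), T)
    elif sc.family == 3:
        head = sc.lambda0 * sc.change_time
        T_trt = np.where(E < head, E / sc.lambda0,
                         sc.change_time + (E - head) / sc.lambda2)
        T = np.where(treated, T_trt, T)
    return T


def generate_trial(sc: SimScenario | str, n: int,
                   seed=None, rng: np.random.Generator | None = None) -> SurvivalDataset:
    """One randomized trial of ``n`` subjects; deterministic given the seed."""
    if isinstance(sc, str):
        sc = scenario(sc)
    if n < 2:
        raise ValueError("n must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    V, U = _draw_latents(sc, n, rng)
    Z = (rng.random(n) < sc.pi).astype(np.int8)
    T = _failure_from_uniform(sc, U, Z == 1)
    C = rng.uniform(0.0, sc.censor_upper, n)
    return SurvivalDataset(
        time=np.minimum(T, C), event=(T <= C).astype(np.int8), arm=Z,
        covariates=V, covariate_names=["cov_v1", "cov_v2"])


def generate_reference(sc: SimScenario | str, n_ref: int, matched: bool = True,
                       seed=None, rng: np.random.Generator | None = None) -> SurvivalDataset:
    """Control-law reference data (arm ≡ 0).

    ``matched=False`` rejection-samples the covariate-truncated
    population ``V₁ < 1, V₂ < 1``.
    """
    if isinstance(sc, str):
        sc = scenario(sc)
    if n_ref < 2:
        raise ValueError("n_ref must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    Vs, Us = [], []
    got = 0
    while got < n_ref:
        batch = n_ref if matched else max(2 * (n_ref - got), 32)
        V, U = _draw_latents(sc, batch, rng)
        if not matched:
            keep = (V[:, 0] < 1.0) & (V[:, 1] < 1.0)
            V, U = V[keep], U[keep]
        Vs.append(V)
        Us.append(U)
        got += V.shape[0]
    V = np.concatenate(Vs)[:n_ref]
    U = np.concatenate(Us)[:n_ref]
    T = -np.log(np.clip(U, 1e-300, None)) / sc.lambda0
    C = rng.uniform(0.0, sc.censor_upper, n_ref)
    return SurvivalDataset(
        time=np.minimum(T, C), event=(T <= C).astype(np.int8),
        arm=np.zeros(n_ref, dtype=np.int8),
        covariates=V, covariate_names=["cov_v1", "cov_v2"])


def _rep_rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based substream: independent of replication order."""
    return np.random.default_rng([int(seed), *map(int, stream)])


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

def simulate_rejection_rates(scenario_id: str, n: int = 500, reps: int = 10000,
                             alpha: float = 0.05, seed: int = 0,
                             tests=("standard", "augmented")) -> dict:
    """Empirical size/power of the tests at fixed n (one Table-1 cell pair)."""
    sc = scenario(scenario_id)
    rej = {t: 0 for t in tests}
    for r in range(reps):
        trial = generate_trial(sc, n, rng=_rep_rng(seed, 1, r))
        if "standard" in tests:
            rej["standard"] += standard_test(trial, sc.tau, alpha).p_value < alpha
        if "augmented" in tests:
            rej["augmented"] += augmented_test(trial, sc.tau, alpha, sc.pi).p_value < alpha
    out = {t: rej[t] / reps for t in tests}
    out["mc_se"] = {t: float(np.sqrt(out[t] * (1 - out[t]) / reps)) for t in tests}
    out.update(scenario=scenario_id, n=n, reps=reps, alpha=alpha)
    return out


def simulate_predicted_power(scenario_id: str, n: int = 500, reps: int = 1000,
                             n_ref: int = 200, matched: bool = True,
                             alpha: float = 0.05, seed: int = 0,
                             known_censoring: bool = False) -> dict:
    """Average design-stage predicted power over reference sets (cPP / mPP).

    For each reference set, S₀ and G are Kaplan–Meier estimated (G from
    the known Uniform(0, 8) law instead if ``known_censoring``), ê² is
    computed from the covariates, and the local power at the scenario's
    true RMST difference is recorded.
    """
    sc = scenario(scenario_id)
    theta_alt = true_rmst_diff(sc)
    if theta_alt == 0:
        raise ValueError("predicted power is undefined at a zero alternative")
    g = censoring_spec(sc) if known_censoring else None
    p_std = np.empty(reps)
    p_aug = np.empty(reps)
    stream = 2 if matched else 3
    for r in range(reps):
        ref = generate_reference(sc, n_ref, matched=matched,
                                 rng=_rep_rng(seed, stream, r))
        inputs = reference_design_inputs(ref, sc.tau, sc.pi, g=g)
        res = predicted_power(theta_alt, n, inputs["sigma_tilde_sq"],
                              inputs["e_sq"], alpha, sc.pi, tau=sc.tau)
        p_std[r] = res.power_standard
        p_aug[r] = res.power_augmented
    return {
        "scenario": scenario_id, "n": n, "reps": reps, "n_ref": n_ref,
        "matched": matched, "theta_alt": theta_alt,
        "standard": float(p_std.mean()), "augmented": float(p_aug.mean()),
        "mc_se": {"standard": float(p_std.std(ddof=1) / np.sqrt(reps)),
                  "augmented": float(p_aug.std(ddof=1) / np.sqrt(reps))},
    }


def simulate_ssr(scenario_id: str, n_mid: int = 200, reps: int = 1000,
                 target_power: float = 0.8, alpha: float = 0.05,
                 n_step: int = 10, n_max: int = 3000, seed: int = 0,
                 theta_alt: float | None = None,
                 tests=("standard", "augmented")) -> dict:
    """Blinded simulate → review → resize → final-test loop (Table-2 cells).

    Per replicate a subject stream is drawn; the first ``n_mid`` subjects
    (followed to τ, arms hidden) drive the blinded re-estimation for each
    requested test, the stream is extended to the largest selected size,
    and each final test runs on its first ``n_final`` subjects.
    """
    sc = scenario(scenario_id)
    if theta_alt is None:
        theta_alt = true_rmst_diff(scenario("2" + sc.copula))
    design = DesignSpec(tau=sc.tau, theta_alt=theta_alt, alpha=alpha,
                        target_power=target_power, pi=sc.pi,
                        n_step=n_step, n_min=n_mid, n_max=n_max)
    rej = {t: np.zeros(reps, dtype=bool) for t in tests}
    n_sel = {t: np.zeros(reps, dtype=int) for t in tests}
    for r in range(reps):
        rng = _rep_rng(seed, 4, r)
        trial = generate_trial(sc, n_mid, rng=rng)
        snapshot = trial.blinded()
        for t in tests:
            review = reestimate_n(snapshot, design, use_augmentation=(t == "augmented"))
            n_sel[t][r] = max(review.n_final, n_mid)
        n_need = max(n_sel[t][r] for t in tests)
        if n_need > n_mid:
            extra = generate_trial(sc, n_need - n_mid, rng=rng)
            trial = _concat(trial, extra)
        for t in tests:
            final = trial.head(n_sel[t][r])
            if t == "standard":
                rej[t][r] = standard_test(final, sc.tau, alpha).p_value < alpha
            else:
                rej[t][r] = augmented_test(final, sc.tau, alpha, sc.pi).p_value < alpha
    out = {"scenario": scenario_id, "n_mid": n_mid, "reps": reps,
           "target_power": target_power, "theta_alt": theta_alt}
    for t in tests:
        q = np.percentile(n_sel[t], [0, 25, 50, 75, 100])
        p = float(rej[t].mean())
        out[t] = {
            "power": p,
            "mc_se": float(np.sqrt(p * (1 - p) / reps)),
            "n_min": int(q[0]), "n_q1": int(q[1]), "n_median": int(q[2]),
            "n_q3": int(q[3]), "n_max": int(q[4]),
        }
    return out


def _concat(a: SurvivalDataset, b: SurvivalDataset) -> SurvivalDataset:
    return SurvivalDataset(
        time=np.concatenate((a.time, b.time)),
        event=np.concatenate((a.event, b.event)),
        arm=None if a.arm is None else np.concatenate((a.arm, b.arm)),
        covariates=np.vstack((a.covariates, b.covariates)) if a.n_covariates else None,
        covariate_names=list(a.covariate_names))


def run_study(config: dict) -> dict[str, pd.DataFrame]:
    """Run a configured operating-characteristics study.

    Config keys (all optional except ``scenarios``)::

        scenarios: ["1a", "2a", ...]
        n: 500            reps: 10000       alpha: 0.05      seed: 0
        tests: ["standard", "augmented"]
        reference: {reps: 1000, n_ref: 200, modes: ["matched", "mismatched"],
                    known_censoring: false}
        ssr: {n_mid: 200, reps: 1000, target_power: 0.8, step: 10}

    Returns ``{"rejection": DataFrame, "predicted_power": DataFrame,
    "ssr": DataFrame}`` (keys present when the corresponding section ran).
    """
    known = {"scenarios", "n", "reps", "alpha", "seed", "tests",
             "reference", "ssr"}
    bad = set(config) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    scenarios = config["scenarios"]
    n = int(config.get("n", 500))
    reps = int(config.get("reps", 10000))
    alpha = float(config.get("alpha", 0.05))
    seed = int(config.get("seed", 0))
    tests = tuple(config.get("tests", ("standard", "augmented")))

    rows = []
    for sid in scenarios:
        res = simulate_rejection_rates(sid, n, reps, alpha, seed, tests)
        truth = true_rmst_diff(scenario(sid))
        for t in tests:
            rows.append({"scenario": sid, "true_diff": round(truth, 4),
                         "test": t, "rejection_rate": res[t],
                         "mc_se": res["mc_se"][t], "n": n, "reps": reps})
    tables = {"rejection": pd.DataFrame(rows)}

    ref_cfg = config.get("reference")
    if ref_cfg:
        rows = []
        for sid in scenarios:
            if true_rmst_diff(scenario(sid)) == 0:
                continue
            for mode in ref_cfg.get("modes", ("matched",)):
                res = simulate_predicted_power(
                    sid, n, int(ref_cfg.get("reps", 1000)),
                    int(ref_cfg.get("n_ref", 200)), mode == "matched",
                    alpha, seed,
                    known_censoring=bool(ref_cfg.get("known_censoring", False)))
                for t in tests:
                    rows.append({"scenario": sid, "mode": mode, "test": t,
                                 "mean_predicted_power": res[t],
                                 "mc_se": res["mc_se"][t]})
        tables["predicted_power"] = pd.DataFrame(rows)

    ssr_cfg = config.get("ssr")
    if ssr_cfg:
        rows = []
        for sid in scenarios:
            res = simulate_ssr(
                sid, int(ssr_cfg.get("n_mid", 200)),
                int(ssr_cfg.get("reps", 1000)),
                float(ssr_cfg.get("target_power", 0.8)), alpha,
                int(ssr_cfg.get("step", 10)),
                int(ssr_cfg.get("n_max", 3000)), seed, tests=tests)
            for t in tests:
                row = {"scenario": sid, "test": t, "n_mid": res["n_mid"],
                       "target_power": res["target_power"]}
                row.update({k: v for k, v in res[t].items()})
                rows.append(row)
        tables["ssr"] = pd.DataFrame(rows)
    return tables
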