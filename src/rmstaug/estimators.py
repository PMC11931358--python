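"""RMST-difference tests: standard and covariate-augmented.

The restricted mean survival time (RMST) of group ``z`` over ``[0, τ]``
is ``θ_z = E{min(T, τ) | Z = z} = ∫_0^τ S_z(t) dt``, estimated by the
area under the group's Kaplan–Meier curve.  The standard test is a Wald
test of ``θ̂ = θ̂_1 − θ̂_0``.  Two consistent estimators of the variance
of ``√n (θ̂ − θ)`` are available:

* a plug-in form integrating the squared tail areas against the
  Nelson–Aalen increments (``var_plugin``), and
* the mean square of per-subject influence scores ``H_i`` built from
  martingale-residual integrals (``var_residual``), the form the
  augmented test reuses.

The augmented estimator subtracts a mean-zero linear function of the
baseline covariates, ``θ̂_aug = θ̂ − n⁻¹ Σ (Z_i − π) ĉᵀ V_i``, with ``ĉ``
the least-squares projection of the influence scores onto the span of
``(Z − π) V``.  Under randomization this cannot bias the estimate and,
at π = 1/2, never increases the estimated variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .curves import ArmComponents, arm_components
from .dataset import SurvivalDataset

__all__ = [
    "RMSTResult",
    "AugmentedResult",
    "RMSTDifference",
    "AugmentedRMSTDifference",
    "rmst_estimate",
    "variance_plugin",
    "subject_scores",
    "standard_test",
    "augmented_test",
    "augmentation_coefficient",
]

#: condition-number ceiling beyond which a covariate Gram matrix is
#: treated as collinear
_COND_LIMIT = 1e10


@dataclass
class RMSTResult:
    """Standard RMST-difference test result.

    Variances are for the √n-scaled estimator; ``se = sqrt(var/n)``.
    """

    tau: float
    n: int
    theta1: float
    theta0: float
    theta_diff: float
    var_plugin: float
    var_residual: float
    scores: np.ndarray
    variance_used: str
    alpha: float
    se: float
    z_stat: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau, "n": self.n,
            "rmst_treatment": self.theta1, "rmst_control": self.theta0,
            "rmst_difference": self.theta_diff,
            "var_plugin": self.var_plugin, "var_residual": self.var_residual,
            "variance_used": self.variance_used, "alpha": self.alpha,
            "se": self.se, "z": self.z_stat, "p_value": self.p_value,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


@dataclass
class AugmentedResult:
    """Augmented RMST-difference test result."""

    base: RMSTResult
    pi: float
    c_hat: np.ndarray
    covariate_names: list[str]
    theta_aug: float
    var_aug: float
    alpha: float
    se: float
    z_stat: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        out = self.base.to_dict()
        out.update({
            "pi": self.pi,
            "c_hat": {k: v for k, v in zip(self.covariate_names, self.c_hat.tolist())},
            "rmst_difference_augmented": self.theta_aug,
            "var_augmented": self.var_aug,
            "se": self.se, "z": self.z_stat, "p_value": self.p_value,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })
        return out


def _wald(theta: float, var: float, n: int, alpha: float):
    if var <= 0:
        raise ValueError("no events within truncation window")
    se = float(np.sqrt(var / n))
    z = theta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    zq = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return se, float(z), p, theta - zq * se, theta + zq * se


def _fit_arms(data: SurvivalDataset, tau: float, extend: str):
    data.require_arms()
    comps: dict[int, ArmComponents] = {}
    for z in (0, 1):
        m = data.arm_mask(z)
        comps[z] = arm_components(data.time[m], data.event[m], tau,
                                  n_total=data.n, extend=extend)
    return comps


def _scores_from_components(data: SurvivalDataset, comps) -> np.ndarray:
    """Per-subject scores H_i: −(own integral) in arm 1, +(own) in arm 0."""
    H = np.zeros(data.n)
    H[data.arm_mask(1)] = -comps[1].subject_integrals
    H[data.arm_mask(0)] = comps[0].subject_integrals
    return H


class RMSTDifference(BaseEstimator):
    """Standard (unaugmented) RMST-difference Wald test.

    Parameters
    ----------
    tau : float
        Truncation time, in the units of the ``time`` column.
    alpha : float, default 0.05
        Two-sided significance level.
    variance : {"residual", "plugin"}, default "residual"
        Which consistent variance estimator drives the test statistic:
        the mean-square of the influence scores (shared with the
        augmented test) or the plug-in integral form.  Both are always
        computed and reported.
    extend : {"flat", "strict"}, default "flat"
        Policy when an arm's follow-up ends before ``tau``.

    Attributes (after :meth:`fit`)
    ------------------------------
    theta1_, theta0_, theta_diff_ : RMST per arm and their difference.
    var_plugin_, var_residual_ : variance estimates of √n(θ̂ − θ).
    scores_ : per-subject influence scores ``H_i``.
    se_, z_, p_value_, ci_ : Wald test quantities.
    result_ : the assembled :class:`RMSTResult`.
    """

    def __init__(self, tau: float = 5.0, alpha: float = 0.05,
                 variance: str = "residual", extend: str = "flat"):
        self.tau = tau
        self.alpha = alpha
        self.variance = variance
        self.extend = extend

    def fit(self, data: SurvivalDataset, y=None) -> "RMSTDifference":
        if not isinstance(data, SurvivalDataset):
            data = SurvivalDataset.from_frame(data)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.variance not in ("residual", "plugin"):
            raise ValueError("variance must be 'residual' or 'plugin'")
        comps = _fit_arms(data, self.tau, self.extend)
        self.theta1_ = comps[1].theta
        self.theta0_ = comps[0].theta
        self.theta_diff_ = self.theta1_ - self.theta0_
        self.var_plugin_ = comps[1].var_term + comps[0].var_term
        self.scores_ = _scores_from_components(data, comps)
        self.var_residual_ = float(np.mean(self.scores_**2))
        var = self.var_residual_ if self.variance == "residual" else self.var_plugin_
        self.se_, self.z_, self.p_value_, lo, hi = _wald(
            self.theta_diff_, var, data.n, self.alpha)
        self.ci_ = (lo, hi)
        self.n_ = data.n
        self._components = comps
        self.result_ = RMSTResult(
            tau=self.tau, n=data.n, theta1=self.theta1_, theta0=self.theta0_,
            theta_diff=self.theta_diff_, var_plugin=self.var_plugin_,
            var_residual=self.var_residual_, scores=self.scores_,
            variance_used=self.variance, alpha=self.alpha, se=self.se_,
            z_stat=self.z_, p_value=self.p_value_, ci_low=lo, ci_high=hi)
        return self


class AugmentedRMSTDifference(BaseEstimator):
    """Covariate-augmented RMST-difference Wald test.

    The augmentation coefficient is
    ``ĉ = {π(1−π) Σ V_i V_iᵀ}⁻¹ Σ (Z_i − π) V_i H_i`` with ``H_i`` the
    per-subject influence scores of the standard estimator; at π = 1/2
    this is the exact least-squares projection of ``H`` on ``(Z − π) V``.

    Parameters
    ----------
    tau, alpha, extend : as in :class:`RMSTDifference`.
    pi : float, default 0.5
        Treatment allocation probability.
    covariates : list of str, optional
        Subset of covariate columns to augment with (default: all).
    standardize : bool, default False
        Scale covariates by their standard deviation before solving the
        normal equations (pure conditioning aid; the estimate ``θ̂_aug``
        is invariant to any invertible linear reparameterization).
    allow_pinv : bool, default False
        Use a pseudo-inverse on a collinear covariate Gram matrix
        instead of raising.
    """

    def __init__(self, tau: float = 5.0, alpha: float = 0.05, pi: float = 0.5,
                 covariates: list[str] | None = None, standardize: bool = False,
                 allow_pinv: bool = False, extend: str = "flat"):
        self.tau = tau
        self.alpha = alpha
        self.pi = pi
        self.covariates = covariates
        self.standardize = standardize
        self.allow_pinv = allow_pinv
        self.extend = extend

    def fit(self, data: SurvivalDataset, y=None) -> "AugmentedRMSTDifference":
        if not isinstance(data, SurvivalDataset):
            data = SurvivalDataset.from_frame(data)
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if self.covariates is not None:
            work = data.select_covariates(self.covariates)
            work.arm = data.arm
        else:
            work = data
        if work.n_covariates < 1:
            raise ValueError("augmentation requires at least one covariate")

        base = RMSTDifference(tau=self.tau, alpha=self.alpha,
                              variance="residual", extend=self.extend).fit(data)
        H = base.scores_
        V = work.covariates
        scale = V.std(axis=0, ddof=0) if self.standardize else np.ones(V.shape[1])
        if self.standardize and np.any(scale == 0):
            scale = np.where(scale == 0, 1.0, scale)
        Vs = V / scale
        zc = work.arm - self.pi
        gram = self.pi * (1 - self.pi) * (Vs.T @ Vs)
        rhs = Vs.T @ (zc * H)
        c_scaled = _solve_gram(gram, rhs, self.allow_pinv)
        c = c_scaled / scale

        aug = zc * (V @ c)
        self.c_hat_ = c
        self.theta_aug_ = base.theta_diff_ - float(np.mean(aug))
        self.var_aug_ = float(np.mean((H - aug) ** 2))
        self.base_result_ = base.result_
        self.se_, self.z_, self.p_value_, lo, hi = _wald(
            self.theta_aug_, self.var_aug_, data.n, self.alpha)
        self.ci_ = (lo, hi)
        self.n_ = data.n
        self.result_ = AugmentedResult(
            base=base.result_, pi=self.pi, c_hat=c,
            covariate_names=list(work.covariate_names),
            theta_aug=self.theta_aug_, var_aug=self.var_aug_,
            alpha=self.alpha, se=self.se_, z_stat=self.z_,
            p_value=self.p_value_, ci_low=lo, ci_high=hi)
        return self


def _solve_gram(gram: np.ndarray, rhs: np.ndarray, allow_pinv: bool) -> np.ndarray:
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        if not allow_pinv:
            raise np.linalg.LinAlgError(
                "collinear covariates: Gram matrix is (near-)singular; "
                "drop redundant columns or pass allow_pinv=True")
        warnings.warn("collinear covariates: using pseudo-inverse", stacklevel=3)
        return np.linalg.pinv(gram) @ rhs
    return np.linalg.solve(gram, rhs)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def rmst_estimate(data: SurvivalDataset, tau: float):
    """(θ̂_1, θ̂_0, θ̂_1 − θ̂_0) from per-arm Kaplan–Meier areas."""
    comps = _fit_arms(data, tau, "flat")
    return comps[1].theta, comps[0].theta, comps[1].theta - comps[0].theta


def variance_plugin(data: SurvivalDataset, tau: float) -> float:
    """Plug-in estimate of Var{√n(θ̂ − θ)}; 0 with a warning if eventless."""
    comps = _fit_arms(data, tau, "flat")
    v = comps[1].var_term + comps[0].var_term
    if v == 0:
        warnings.warn("no events within [0, tau]; variance degenerates to 0",
                      stacklevel=2)
    return v


def subject_scores(data: SurvivalDataset, tau: float):
    """Per-subject influence scores H_i and the residual variance n⁻¹ΣH_i²."""
    comps = _fit_arms(data, tau, "flat")
    H = _scores_from_components(data, comps)
    return H, float(np.mean(H**2))


def standard_test(data: SurvivalDataset, tau: float, alpha: float = 0.05,
                  variance: str = "residual") -> RMSTResult:
    return RMSTDifference(tau=tau, alpha=alpha, variance=variance).fit(data).result_


def augmented_test(data: SurvivalDataset, tau: float, alpha: float = 0.05,
                   pi: float = 0.5, covariates: list[str] | None = None,
                   **kwargs) -> AugmentedResult:
    return AugmentedRMSTDifference(tau=tau, alpha=alpha, pi=pi,
                                   covariates=covariates, **kwargs).fit(data).result_


def augmentation_coefficient(data: SurvivalDataset, tau: float,
                             pi: float = 0.5) -> np.ndarray:
    return AugmentedRMSTDifference(tau=tau, pi=pi).fit(data).c_hat_
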