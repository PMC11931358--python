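"""Blinded mid-trial sample-size re-estimation.

At an early blinded review with ``n_mid`` subjects followed to ``τ``,
the two arms are pooled (treatment labels never read): the pooled
Kaplan–Meier estimates ``S₀``, the pooled reverse Kaplan–Meier estimates
the censoring law ``G``, and ``ê²`` is recomputed from the pooled
martingale residuals under the pooled (null) Nelson–Aalen fit.  The
local-power formula is then scanned over ``n = n_mid, n_mid+step, …``
and the first ``n`` reaching the target power is adopted.  Because the
local power does not involve the treatment assignment, this adaptation
preserves blinding and leaves the type-I error essentially untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import SurvivalDataset
from .power import (DesignSpec, KMCurveSpec, e_squared, predicted_power,
                    sigma_tilde_residual, sigma_tilde_sq)

__all__ = ["BlindedReview", "blinded_inputs", "reestimate_n"]


@dataclass
class BlindedReview:
    """Outcome of a blinded sample-size review."""

    n_mid: int
    sigma_tilde_sq: float
    e_sq: float
    augmented: bool
    design: DesignSpec
    n_final: int
    grid: np.ndarray
    grid_power: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_mid": self.n_mid,
            "sigma_tilde_sq": self.sigma_tilde_sq,
            "e_sq": self.e_sq,
            "augmented": self.augmented,
            "target_power": self.design.target_power,
            "theta_alt": self.design.theta_alt,
            "n_final": self.n_final,
            "power_table": [
                {"n": int(n), "power": float(p)}
                for n, p in zip(self.grid, self.grid_power)
            ],
        }


def _check_blinded(pooled: SurvivalDataset, unblind_ok: bool) -> SurvivalDataset:
    if pooled.arm is not None:
        if not unblind_ok:
            raise ValueError(
                "blinded review received data with an arm column; strip it "
                "(dataset.blinded()) or pass unblind_ok=True to discard it")
        pooled = pooled.blinded()
    return pooled


def blinded_inputs(pooled: SurvivalDataset, tau: float,
                   unblind_ok: bool = False,
                   covariates: list[str] | None = None,
                   pi: float = 0.5):
    """(S₀ spec, G spec, ê²) from a pooled, treatment-blinded snapshot."""
    pooled = _check_blinded(pooled, unblind_ok)
    if float(np.max(pooled.time)) < tau:
        warnings.warn(
            "pooled follow-up ends before tau; pooled Kaplan-Meier curves "
            "extended flat — re-estimated quantities may be unreliable",
            stacklevel=2)
    s0 = KMCurveSpec.from_data(pooled.time, pooled.event)
    g = KMCurveSpec.censoring_from_data(pooled.time, pooled.event)
    work = pooled.select_covariates(covariates) if covariates else pooled
    e2 = e_squared(work, tau, pooled=True, pi=pi) if work.n_covariates else 0.0
    return s0, g, e2


def reestimate_n(pooled: SurvivalDataset, design: DesignSpec,
                 use_augmentation: bool = False,
                 unblind_ok: bool = False,
                 covariates: list[str] | None = None,
                 variance_form: str = "residual") -> BlindedReview:
    """Re-estimate the final sample size from a blinded snapshot.

    Scans ``n = n_mid, n_mid + step, …`` (never below the subjects already
    observed) and returns the first ``n`` whose predicted power reaches the
    target, together with the whole power-versus-n table.  σ̃₁² is taken
    in the score form by default (``variance_form="plugin"`` switches to
    the Kaplan–Meier integral form).
    """
    pooled = _check_blinded(pooled, unblind_ok)
    n_mid = pooled.n
    s0, g, e2 = blinded_inputs(pooled, design.tau, covariates=covariates,
                               pi=design.pi)
    if variance_form == "residual":
        st2 = sigma_tilde_residual(pooled.time, pooled.event, design.tau,
                                   design.pi)
    else:
        st2 = sigma_tilde_sq(s0, g, design.tau, design.pi)
    grid = np.arange(n_mid, design.n_max + 1, design.n_step)
    p_std, p_aug = predicted_power(design.theta_alt, grid, st2,
                                   e2 if use_augmentation else 0.0,
                                   design.alpha, design.pi)
    powers = p_aug if use_augmentation else p_std
    hit = np.nonzero(powers >= design.target_power)[0]
    if hit.size == 0:
        raise ValueError(
            f"target power {design.target_power} not reached by n_max="
            f"{design.n_max} (power there: {powers[-1]:.4f}; "
            f"sigma_tilde_sq={st2:.4g}, e_sq={e2:.4g})")
    n_final = int(grid[hit[0]])
    return BlindedReview(n_mid=n_mid, sigma_tilde_sq=st2, e_sq=e2,
                         augmented=use_augmentation, design=design,
                         n_final=n_final, grid=grid, grid_power=powers)
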