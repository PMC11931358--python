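"""Subject-level survival data container.

A trial record is one row per subject: follow-up time ``X = min(T, C)``,
event indicator ``Δ = 1{T ≤ C}``, treatment arm ``Z ∈ {0, 1}`` and an
optional matrix of numeric baseline covariates ``V``.  Reference data
(all-control) and blinded pooled snapshots are the same container with
``arm`` absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]


@dataclass
class SurvivalDataset:
    """Right-censored two-arm survival data with optional covariates.

    Parameters
    ----------
    time : array of shape (n,)
        Nonnegative follow-up times, in the same units as the truncation
        time ``tau`` used downstream.
    event : array of shape (n,)
        1 if the event was observed, 0 if the subject was censored.
    arm : array of shape (n,), or None
        1 = treatment, 0 = control.  ``None`` marks a blinded/pooled or
        single-group dataset.
    covariates : array of shape (n, p), optional
        Numeric baseline covariates; ``p = 0`` is allowed.  Missing values
        are rejected: rows must be filtered before construction.
    covariate_names : list of str, optional
    ids : array-like, optional
        Opaque subject labels.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = self.time.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            bad = int(np.argmax(~np.isfinite(self.time) | (self.time < 0)))
            raise ValueError(f"negative or non-finite time at row {bad}")
        self.event = _as_binary(self.event, "event", n)
        if self.arm is not None:
            self.arm = _as_binary(self.arm, "arm", n)
        if self.covariates is not None:
            V = np.asarray(self.covariates, dtype=float)
            if V.ndim == 1:
                V = V[:, None]
            if V.shape[0] != n:
                raise ValueError("covariates and time lengths differ")
            if np.any(~np.isfinite(V)):
                raise ValueError(
                    "covariates contain missing or non-finite values; "
                    "drop incomplete rows before constructing the dataset"
                )
            self.covariates = V
            if not self.covariate_names:
                self.covariate_names = [f"cov_{j + 1}" for j in range(V.shape[1])]
            if len(self.covariate_names) != V.shape[1]:
                raise ValueError("covariate_names length mismatch")
        else:
            self.covariates = np.empty((n, 0))

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def require_arms(self) -> None:
        if self.arm is None:
            raise ValueError("dataset has no arm labels")
        if not (np.any(self.arm == 1) and np.any(self.arm == 0)):
            raise ValueError("no subjects in arm " + ("1" if not np.any(self.arm == 1) else "0"))

    def arm_mask(self, z: int) -> np.ndarray:
        if self.arm is None:
            raise ValueError("dataset has no arm labels")
        return self.arm == z

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            time=self.time[mask],
            event=self.event[mask],
            arm=None if self.arm is None else self.arm[mask],
            covariates=self.covariates[mask] if self.n_covariates else None,
            covariate_names=list(self.covariate_names),
            ids=None if self.ids is None else np.asarray(self.ids)[mask],
        )

    def head(self, k: int) -> "SurvivalDataset":
        """First ``k`` subjects in enrollment order."""
        mask = np.zeros(self.n, dtype=bool)
        mask[:k] = True
        return self.subset(mask)

    def blinded(self) -> "SurvivalDataset":
        """Copy with the arm column stripped, for blinded analyses."""
        out = self.subset(np.ones(self.n, dtype=bool))
        out.arm = None
        return out

    def select_covariates(self, names: list[str]) -> "SurvivalDataset":
        idx = [self.covariate_names.index(c) for c in names]
        return SurvivalDataset(
            time=self.time,
            event=self.event,
            arm=self.arm,
            covariates=self.covariates[:, idx] if idx else None,
            covariate_names=list(names),
            ids=self.ids,
        )

    # -- pandas bridge ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data: dict = {"time": self.time, "event": self.event}
        if self.arm is not None:
            data["arm"] = self.arm
        for j, name in enumerate(self.covariate_names):
            data[name] = self.covariates[:, j]
        if self.ids is not None:
            data["id"] = self.ids
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        event_col: str = "event",
        arm_col: str | None = "arm",
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalDataset":
        for col in (time_col, event_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c.startswith("cov_")]
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing covariate columns {missing}")
        arm = None
        if arm_col is not None and arm_col in df.columns:
            arm = df[arm_col].to_numpy()
        return cls(
            time=df[time_col].to_numpy(dtype=float),
            event=df[event_col].to_numpy(),
            arm=arm,
            covariates=df[covariate_cols].to_numpy(dtype=float) if covariate_cols else None,
            covariate_names=list(covariate_cols),
            ids=df["id"].to_numpy() if "id" in df.columns else None,
        )


def _as_binary(x, name: str, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},)")
    vals = np.unique(x[~pd.isna(x)])
    if pd.isna(x).any() or not np.all(np.isin(vals.astype(float), (0.0, 1.0))):
        raise ValueError(f"{name} must be coded 0/1")
    return x.astype(np.int8)
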