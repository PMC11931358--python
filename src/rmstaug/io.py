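"""Delimited-text readers/writers and JSON result serialization."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset

__all__ = ["read_dataset", "write_dataset", "write_json"]

log = logging.getLogger("rmstaug")


def read_dataset(path, time_col: str = "time", event_col: str = "event",
                 arm_col: str | None = "arm",
                 covariate_cols: list[str] | None = None,
                 delimiter: str | None = None) -> SurvivalDataset:
    """Load a subject-level CSV/TSV file.

    Columns default to ``time``, ``event``, ``arm`` and every column with
    a ``cov_`` prefix.  Rows with missing covariate values are dropped
    with a logged count; missing time/event values are an error.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0])
            raise ValueError(f"missing {col!r} value at row {row} in {path}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c.startswith("cov_")]
    if covariate_cols:
        complete = df[covariate_cols].notna().all(axis=1)
        dropped = int((~complete).sum())
        if dropped:
            log.warning("dropped %d rows with missing covariate values", dropped)
            df = df[complete].reset_index(drop=True)
    bad_time = df[time_col] < 0
    if bad_time.any():
        row = int(df[bad_time].index[0])
        raise ValueError(f"negative time at row {row} in {path}")
    return SurvivalDataset.from_frame(df, time_col, event_col, arm_col,
                                      covariate_cols)


def write_dataset(dataset: SurvivalDataset, path, delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # default float repr is shortest-round-trip; the reader must use
    # float_precision="round_trip" to recover values bit-exactly
    dataset.to_frame().to_csv(path, sep=delimiter, index=False)


def write_json(payload: dict, path=None) -> str:
    """Serialize a result record (with numpy scalars/arrays) to JSON."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    text = json.dumps(payload, indent=2, default=default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
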