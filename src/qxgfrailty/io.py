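"""Dataset I/O: CSV survival tables and univariate loss samples."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_survival_table", "read_loss_sample"]


def read_survival_table(path) -> pd.DataFrame:
    """Read a right-censored survival table from CSV.

    Requires a header with columns ``time`` and ``status``; any further
    columns are treated as covariates.  Validation failures report the
    offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    problems = []
    t = pd.to_numeric(df["time"], errors="coerce")
    bad_t = df.index[~np.isfinite(t) | (t <= 0)]
    for i in bad_t:
        problems.append(f"row {i + 1}: time must be a positive number, got {df['time'][i]!r}")
    s = pd.to_numeric(df["status"], errors="coerce")
    bad_s = df.index[~s.isin([0, 1])]
    for i in bad_s:
        problems.append(f"row {i + 1}: status must be 0 or 1, got {df['status'][i]!r}")
    covs = [c for c in df.columns if c not in ("time", "status")]
    for c in covs:
        v = pd.to_numeric(df[c], errors="coerce")
        for i in df.index[~np.isfinite(v)]:
            problems.append(f"row {i + 1}: covariate {c!r} not numeric, got {df[c][i]!r}")
    if problems:
        raise ValueError(f"{path}: invalid survival table:\n" + "\n".join(problems))
    out = df[["time", "status", *covs]].copy()
    out["time"] = t
    out["status"] = s.astype(int)
    for c in covs:
        out[c] = pd.to_numeric(df[c])
    return out


def read_loss_sample(path) -> np.ndarray:
    """Read a univariate positive loss sample (one value per line, no header)."""
    vals = np.loadtxt(path, dtype=float, ndmin=1)
    if vals.ndim != 1:
        raise ValueError(f"{path}: expected one value per line")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: loss values must be positive and finite")
    return vals
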