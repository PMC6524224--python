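"""Delimited-text readers and writers for subject tables, curves and reports.

Subject files carry one row per patient with header
``id,time,status,cause,age_dx,sex,year_dx,<covariate...>``; ``cause`` may be
empty (population-based estimators do not need it).  Times are in years.
Curve files carry ``time,estimate,var,lo,hi``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import SurvivalCurve

__all__ = ["read_subjects", "write_subjects", "read_curve", "write_curve",
           "write_report", "read_report"]

SUBJECT_REQUIRED = ("id", "time", "status")


def read_subjects(source, sep: str = ",") -> pd.DataFrame:
    """Read and validate a subject table.

    status must be 0/1; cause 0/1 or empty; time >= 0.  Violations raise
    with the offending row numbers (0-based, excluding the header).
    """
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in SUBJECT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"subject file missing column(s): {missing}")
    bad = df.index[df["time"].isna() | (df["time"] < 0)].tolist()
    if bad:
        raise ValueError(f"invalid time (missing or negative) in row(s) {bad}")
    bad = df.index[~df["status"].isin([0, 1])].tolist()
    if bad:
        raise ValueError(f"status must be 0 or 1; bad row(s) {bad}")
    if "cause" in df.columns:
        present = df["cause"].notna()
        bad = df.index[present & ~df.loc[present, "cause"].isin([0, 1])].tolist()
        if bad:
            raise ValueError(f"cause must be 0, 1 or empty; bad row(s) {bad}")
        bad = df.index[present & (df["cause"] == 1) & (df["status"] == 0)].tolist()
        if bad:
            raise ValueError(f"cause = 1 requires status = 1; bad row(s) {bad}")
    return df


def write_subjects(df: pd.DataFrame, dest, sep: str = ",") -> None:
    df.to_csv(dest, sep=sep, index=False)


def write_curve(curve: SurvivalCurve, dest, sep: str = ",") -> None:
    curve.to_frame().to_csv(dest, sep=sep, index=False)


def read_curve(source, sep: str = ",") -> SurvivalCurve:
    df = pd.read_csv(source, sep=sep)
    return SurvivalCurve(times=df["time"].to_numpy(),
                         estimate=df["estimate"].to_numpy(),
                         variance=df["var"].to_numpy(),
                         ci_low=df["lo"].to_numpy(),
                         ci_high=df["hi"].to_numpy())


REPORT_COLUMNS = ["method", "misclass", "time", "bias", "rbias", "rmse",
                  "ecr", "n_used", "n_failed"]


def write_report(perf, dest, sep: str = ",") -> None:
    """Write the net-survival criteria table with a stable column order."""
    df = perf.survival if hasattr(perf, "survival") else perf
    cols = [c for c in REPORT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(dest, sep=sep, index=False)


def read_report(source, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(source, sep=sep)
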