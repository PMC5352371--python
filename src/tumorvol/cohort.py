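"""Patient cohort table: typed records, validation, CSV round-trips.

A cohort is a thin wrapper over a pandas DataFrame with one row per
patient.  Required columns are ``id`` and the binary endpoint ``pcr``;
clinical covariates (age, sex, cT, cN, CCRT-to-surgery interval, dose
schedule, chemotherapy regimen) and volumetric features (rtv_cm3,
compactness, catv_cm3, tctv_cm3) are carried when present.  Clinical
nodal stage is binarized for modelling as ``cn_pos`` = 1 for cN1-2, 0 for
cN0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["Cohort", "read_cohort", "write_cohort", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("id", "pcr")
ENDPOINT_COLUMNS = ("pcr", "pn_pos", "lvsi")
FEATURE_COLUMNS = ("rtv_cm3", "compactness", "catv_cm3", "tctv_cm3", "sa_rtv_cm3")


@dataclass
class Cohort:
    """Validated per-patient table; ``df`` has one row per unique patient id."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate(self.df.copy())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_pcr(self) -> int:
        return int(self.df["pcr"].sum())

    def subgroup(self, column: str, value) -> "Cohort":
        if column not in self.df.columns:
            raise SchemaError(f"subgroup column {column!r} not in cohort")
        return Cohort(self.df[self.df[column] == value].reset_index(drop=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError("cohort is missing required column(s): " + ", ".join(missing))
    errors: list[str] = []
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        errors.append(f"duplicate patient ids: {dup[:5]}")
    for col in ENDPOINT_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin([0, 1, 0.0, 1.0, True, False])
        if bad.any():
            rows = vals.index[bad].tolist()
            errors.append(f"endpoint {col!r} must be binary 0/1; bad rows {rows[:5]}")
        else:
            df[col] = df[col].astype("Int64") if df[col].isna().any() else df[col].astype(int)
    if "cN" in df.columns:
        vals = df["cN"].dropna()
        bad = ~vals.isin([0, 1, 2])
        if bad.any():
            errors.append(f"cN must be 0/1/2; bad rows {vals.index[bad].tolist()[:5]}")
        elif "cn_pos" not in df.columns:
            df["cn_pos"] = (df["cN"] > 0).astype(int)
    if errors:
        raise SchemaError("; ".join(errors))
    return df


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    return Cohort(pd.read_csv(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)
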