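"""Observation-table file format, run configuration, validation.

The canonical on-disk format is a comma-separated UTF-8 CSV with a required
header, one row per trial/measurement, and missing values written as empty
strings.  A row may carry an empty ``value`` with covariates present: such
rows declare a unit whose response is missing and are integrated out during
model fitting.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COLUMNS",
    "TRAITS",
    "RunConfig",
    "read_observations",
    "write_observations",
    "ValidationError",
]

COLUMNS = [
    "observation_id",
    "individual_id",
    "biological_mother_id",
    "rearing_mother_id",
    "trait",
    "value",
    "age_months",
    "sex",
    "year",
    "cohort",
    "gps_east_m",
    "group_size",
    "companion_class",
    "test_number",
    "days_since_prev_test",
    "observer_id",
]

TRAITS = ["py_movement", "subadult_fid", "subadult_survival", "adult_female_fid"]

COMPANION_CLASSES = [
    "alone",
    "mother_present",
    "small_py",
    "medium_py",
    "large_py",
    "yearling",
]

_STRING_COLUMNS = [
    "observation_id",
    "individual_id",
    "biological_mother_id",
    "rearing_mother_id",
    "trait",
    "sex",
    "companion_class",
    "observer_id",
]
_NUMERIC_COLUMNS = [
    "value",
    "age_months",
    "year",
    "cohort",
    "gps_east_m",
    "group_size",
    "test_number",
    "days_since_prev_test",
]


class ValidationError(ValueError):
    """Raised when an observation table violates the format contract."""


def _line(df_index: int) -> int:
    # +2: one for the header, one for 0-based indexing
    return int(df_index) + 2


def read_observations(
    path, n_py_stages: int = 8, strict_scores: bool = True
) -> pd.DataFrame:
    """Read and validate an observation table from CSV.

    Checks the canonical header, coerces types, and verifies row-level
    invariants (binary survival values, pouch-young scores on the
    1/n_py_stages grid, a single biological mother per individual),
    reporting offending line numbers.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")
    df = raw[COLUMNS].copy()
    for col in _STRING_COLUMNS:
        df[col] = df[col].replace("", np.nan)
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = coerced.isna() & df[col].replace("", np.nan).notna()
        if bad.any():
            i = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric {col} value {raw[col][i]!r} on line {_line(i)}"
            )
        df[col] = coerced
    return validate_observations(df, n_py_stages=n_py_stages,
                                 strict_scores=strict_scores, origin=str(path))


def validate_observations(
    df: pd.DataFrame,
    n_py_stages: int = 8,
    strict_scores: bool = True,
    origin: str = "table",
) -> pd.DataFrame:
    unknown = set(df["trait"].dropna()) - set(TRAITS)
    if unknown:
        i = df.index[df["trait"].isin(unknown)][0]
        raise ValidationError(
            f"{origin}: unknown trait {df['trait'][i]!r} on line {_line(i)}"
        )
    surv = df[(df["trait"] == "subadult_survival") & df["value"].notna()]
    bad = surv[~surv["value"].isin([0.0, 1.0])]
    if len(bad):
        i = bad.index[0]
        raise ValidationError(
            f"{origin}: survival value {bad['value'][i]} on line {_line(i)} "
            "is not binary"
        )
    if strict_scores:
        py = df[(df["trait"] == "py_movement") & df["value"].notna()]
        grid = py["value"] * n_py_stages
        off = py[(np.abs(grid - np.round(grid)) > 1e-9) | (py["value"] < 0)
                 | (py["value"] > 1)]
        if len(off):
            i = off.index[0]
            raise ValidationError(
                f"{origin}: py_movement value {off['value'][i]} on line "
                f"{_line(i)} is not a multiple of 1/{n_py_stages} in [0, 1]"
            )
    mothers = df.dropna(subset=["biological_mother_id"]).groupby("individual_id")[
        "biological_mother_id"
    ].nunique()
    multi = mothers[mothers > 1]
    if len(multi):
        raise ValidationError(
            f"{origin}: individual {multi.index[0]!r} has "
            f"{multi.iloc[0]} distinct biological mothers"
        )
    return df


def write_observations(table: pd.DataFrame, path) -> None:
    """Write an observation table as canonical CSV (empty string for NA)."""
    out = table[COLUMNS].copy()
    for col in ["year", "cohort", "group_size", "test_number"]:
        # keep integer-valued columns free of trailing .0 in the CSV
        v = out[col]
        if v.notna().all() and np.allclose(v % 1, 0):
            out[col] = v.astype(int)
    out.to_csv(path, index=False, na_rep="")


_RUNCONFIG_KEYS = {
    "input",
    "output_dir",
    "model",
    "verbosity",
    "mcmc",
    "simulation",
}


@dataclass
class RunConfig:
    """Parsed run configuration (strict: unknown keys are rejected)."""

    input: str | None = None
    output_dir: str = "."
    model: str = "both"  # "I", "II" or "both"
    verbosity: int = 1
    mcmc: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(data) - _RUNCONFIG_KEYS
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.model not in ("I", "II", "both"):
            raise ValidationError(f"{path}: model must be 'I', 'II' or 'both'")
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:12]
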