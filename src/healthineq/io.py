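"""Reading, validation and deterministic writing of the interchange tables.

Everything travels as flat UTF-8 CSV/TSV: person-level microdata, country
macro indicators, the reference age structure, and the stage outputs
(prevalence, index and decomposition tables).  Readers validate column names,
types and categorical vocabularies and fail with the offending column/value;
writers emit a fixed column order and fixed decimal formatting — four
decimals for index values, one for percentages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import AGE_BANDS, DOMAINS, EDUCATION_LEVELS

__all__ = [
    "read_microdata", "write_microdata",
    "read_macro", "write_macro",
    "read_reference_ages", "write_reference_ages",
    "write_table", "format_index", "format_percent",
]

_VOCAB = {
    "age_band": AGE_BANDS,
    "gender": ["male", "female"],
    "marital": ["married", "other"],
    "education": EDUCATION_LEVELS,
}
_STRING_COLUMNS = ["country_code", "household_id", "stratum_id", "cluster_id",
                   "age_band", "gender", "marital", "education"]
_BINARY_COLUMNS = ["chronic", "smoke", "drink", "adl", "iadl", "mobility"]

MICRODATA_COLUMNS = (
    ["person_id"] + _STRING_COLUMNS[:4] + ["sample_weight", "age_years", "age_band"]
    + _STRING_COLUMNS[5:] + _BINARY_COLUMNS[:3] + ["income_pc"] + _BINARY_COLUMNS[3:]
)

MACRO_COLUMNS = ["country_code", "hospital_beds_per_1000", "sanitation_pct",
                 "rural_pct", "health_exp_pct_gdp", "tertiary_enrolment_pct", "gdp"]


def format_index(x: float) -> str:
    """Four-decimal formatting of index values, e.g. -0.08571349 -> '-0.0857'."""
    return f"{x:.4f}"


def format_percent(x: float) -> str:
    """One-decimal formatting of percentages."""
    return f"{x:.1f}"


def read_microdata(path) -> pd.DataFrame:
    """Read and validate person-level survey microdata from CSV."""
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLUMNS})
    missing = [c for c in MICRODATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"microdata file lacks required column(s): {missing}")
    extra = [c for c in df.columns if c not in MICRODATA_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown microdata column(s): {extra}", UserWarning)
        df = df[MICRODATA_COLUMNS]

    for col, levels in _VOCAB.items():
        vals = df[col].dropna()
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise ValueError(
                f"column {col!r} contains value(s) outside its vocabulary: {bad}; "
                f"expected one of {levels}")
    for col in _STRING_COLUMNS:
        df[col] = df[col].astype(object)

    df["person_id"] = df["person_id"].astype(np.int64)
    df["age_years"] = df["age_years"].astype(np.int64)
    if (df["age_years"] < 55).any():
        row = int(df.index[df["age_years"] < 55][0])
        raise ValueError(f"age_years below 55 at row {row}")
    df["sample_weight"] = df["sample_weight"].astype(float)
    if (df["sample_weight"] <= 0).any():
        row = int(df.index[df["sample_weight"] <= 0][0])
        raise ValueError(f"nonpositive sample_weight at row {row}")
    df["income_pc"] = df["income_pc"].astype(float)
    if (df["income_pc"] < 0).any():
        row = int(df.index[df["income_pc"] < 0][0])
        raise ValueError(f"negative income_pc at row {row}")
    for col in _BINARY_COLUMNS:
        vals = df[col].astype("Int64")
        bad = vals.dropna().isin((0, 1))
        if not bad.all():
            raise ValueError(f"column {col!r} must be binary 0/1; "
                             f"offending value {vals.dropna()[~bad].iloc[0]}")
        df[col] = vals
    return df


def write_microdata(df: pd.DataFrame, path) -> None:
    """Write microdata as UTF-8 CSV in the documented fixed column order."""
    df[MICRODATA_COLUMNS].to_csv(path, index=False)


def read_macro(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_code": "string"})
    missing = [c for c in MACRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"macro file lacks required column(s): {missing}")
    df = df[MACRO_COLUMNS].copy()
    df["country_code"] = df["country_code"].astype(object)
    if df["country_code"].duplicated().any():
        dup = df.loc[df["country_code"].duplicated(), "country_code"].iloc[0]
        raise ValueError(f"duplicate macro row for country {dup}")
    for col in MACRO_COLUMNS[1:]:
        df[col] = df[col].astype(float)
    for col in ("sanitation_pct", "rural_pct", "tertiary_enrolment_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValueError(f"column {col!r} must lie in [0, 100]")
    return df


def write_macro(df: pd.DataFrame, path) -> None:
    df[MACRO_COLUMNS].to_csv(path, index=False)


def read_reference_ages(path) -> pd.Series:
    """Read the 2-column (age_band, share) reference age structure."""
    df = pd.read_csv(path, dtype={"age_band": "string"})
    for col in ("age_band", "share"):
        if col not in df.columns:
            raise ValueError(f"reference age file lacks column {col!r}")
    bad = sorted(set(df["age_band"]) - set(AGE_BANDS))
    if bad:
        raise ValueError(f"unknown age band(s) in reference file: {bad}")
    s = pd.Series(df["share"].astype(float).to_numpy(),
                  index=pd.Index(df["age_band"].astype(object), name="age_band"),
                  name="share")
    if (s < 0).any():
        raise ValueError("reference shares must be nonnegative")
    if abs(s.sum() - 1.0) > 1e-6:
        raise ValueError(f"reference shares sum to {s.sum()}, expected 1")
    return s


def write_reference_ages(ref: pd.Series, path) -> None:
    ref.rename("share").rename_axis("age_band").reset_index().to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, formats: dict | None = None,
                sep: str = "\t") -> None:
    """Write a results table deterministically with per-column formatting.

    ``formats`` maps column name -> one of {"index", "percent"} or a printf
    pattern; unlisted columns are written as-is.
    """
    out = df.copy()
    for col, fmt in (formats or {}).items():
        if col not in out.columns:
            continue
        if fmt == "index":
            out[col] = out[col].map(format_index)
        elif fmt == "percent":
            out[col] = out[col].map(format_percent)
        else:
            out[col] = out[col].map(lambda x: fmt % x)
    out.to_csv(path, sep=sep, index=False)
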