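"""Reading, writing and validating the district-month CSV schema.

Schema (UTF-8, header required, empty string = missing value)::

    district_id,region,area_type,population,period,service,value,
    reports_expected,reports_actual

``value`` is the reported monthly count; ``reports_expected`` /
``reports_actual`` carry the facility reporting-form metadata from which
completeness is derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .periods import check_period

SCHEMA = [
    "district_id",
    "region",
    "area_type",
    "population",
    "period",
    "service",
    "value",
    "reports_expected",
    "reports_actual",
]

AREA_TYPES = ("urban", "rural", "mixed")

DTYPES = {
    "district_id": str,
    "region": str,
    "area_type": str,
    "service": str,
}


def read_dataset(path) -> pd.DataFrame:
    """Read a district-month dataset CSV into the canonical frame."""
    df = pd.read_csv(path, dtype=DTYPES, keep_default_na=False, na_values=[""])
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    df = df[SCHEMA].copy()
    df["population"] = pd.to_numeric(df["population"])
    df["period"] = df["period"].astype(int)
    df["value"] = pd.to_numeric(df["value"])
    df["reports_expected"] = df["reports_expected"].astype(int)
    df["reports_actual"] = df["reports_actual"].astype(int)
    return df


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write a dataset CSV that round-trips losslessly through read_dataset.

    Missing counts are written as empty fields, never as "0".
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty dataset")
    out = records[SCHEMA].copy()
    # keep integer formatting for integral counts so the CSV is stable
    out["value"] = out["value"].map(_fmt_count)
    out.to_csv(path, index=False, na_rep="")


def _fmt_count(v) -> str:
    if pd.isna(v):
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def completeness(df: pd.DataFrame) -> pd.Series:
    """Per-record reporting completeness c = actual/expected (NaN when expected==0)."""
    exp = df["reports_expected"].to_numpy(dtype=float)
    act = df["reports_actual"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(exp > 0, act / exp, np.nan)
    return pd.Series(c, index=df.index, name="completeness")


def validate_input(df: pd.DataFrame) -> list[dict]:
    """Structural checks; returns a list of problem dicts (empty = clean).

    Each problem has keys: row (0-based data row), column, message.
    """
    problems: list[dict] = []

    def add(rows, column, message):
        for r in np.atleast_1d(rows):
            problems.append({"row": int(r), "column": column, "message": message})

    bad_area = ~df["area_type"].isin(AREA_TYPES)
    add(df.index[bad_area], "area_type",
        f"area_type must be one of {AREA_TYPES}")

    for i, p in df["period"].items():
        try:
            check_period(p)
        except ValueError as e:
            add(i, "period", str(e))

    add(df.index[df["reports_actual"] > df["reports_expected"]],
        "reports_actual", "reports_actual exceeds reports_expected")
    add(df.index[df["reports_expected"] < 0], "reports_expected",
        "reports_expected is negative")
    add(df.index[df["value"] < 0], "value", "negative count")
    add(df.index[df["population"] <= 0], "population", "population must be positive")

    key = ["district_id", "period", "service"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        for _, grp in df[dup].groupby(key):
            rows = list(grp.index)
            add(rows, "key",
                f"duplicate (district_id, period, service) at rows {rows}")
    return problems
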