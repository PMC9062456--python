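"""Data-quality assessment: reporting completeness, missing values, outliers.

Three kinds of flags are produced:

* ``low_completeness`` — district-month-service with facility reporting
  completeness strictly below a threshold (default 0.75);
* ``missing`` — a cell of the district x period x service lattice with no
  reported value (a reported zero is a value, not missing);
* ``outlier`` — a monthly value whose modified Z-score against the annual
  median of its district-service series exceeds a cutoff (default 5).

The modified Z-score is ``0.6745 * |x - median| / MAD``; when the MAD is
zero the mean absolute deviation is used instead, and when that is also
zero nothing is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .periods import period_year

MODIFIED_Z_CONSTANT = 0.6745
OUTLIER_CUTOFF = 5.0
LOW_COMPLETENESS = 0.75
MODERATE_COMPLETENESS = 0.90

FLAG_KINDS = ("low_completeness", "missing", "outlier")


@dataclass(frozen=True)
class QualityFlag:
    district_id: str
    period: int
    service: str
    kind: str
    score: float | None = None
    threshold: float | None = None


def flags_to_frame(flags: list[QualityFlag]) -> pd.DataFrame:
    cols = ["district_id", "period", "service", "kind", "score", "threshold"]
    if not flags:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([f.__dict__ for f in flags])[cols]


def modified_z_scores(values, constant: float = MODIFIED_Z_CONSTANT) -> np.ndarray:
    """Modified Z-score of each value against the series median.

    NaNs get a NaN score.  Falls back from MAD to the mean absolute
    deviation when the MAD is zero; all-zero deviations give zero scores.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values to score outliers")
    med = float(np.median(obs))
    dev = np.abs(x - med)
    mad = float(np.median(np.abs(obs - med)))
    if mad == 0.0:
        mad = float(np.mean(np.abs(obs - med)))
    if mad == 0.0:
        return np.where(np.isnan(x), np.nan, 0.0)
    with np.errstate(over="ignore"):   # subnormal MAD can overflow to inf
        return constant * dev / mad


def detect_outliers(series, district_id: str = "", service: str = "",
                    periods=None, cutoff: float = OUTLIER_CUTOFF,
                    constant: float = MODIFIED_Z_CONSTANT) -> list[QualityFlag]:
    """Flag values of one district-service-year series with score > cutoff."""
    x = np.asarray(series, dtype=float)
    if np.all(np.isnan(x)):
        warnings.warn("all-missing series: outlier detection is a no-op")
        return []
    if periods is None:
        periods = list(range(1, len(x) + 1))
    scores = modified_z_scores(x, constant=constant)
    flags = []
    for i, s in enumerate(scores):
        # an overflowed (infinite) score is still decisively above the cutoff
        if not np.isnan(s) and s > cutoff:
            flags.append(QualityFlag(district_id, int(periods[i]), service,
                                     "outlier", score=float(s), threshold=cutoff))
    return flags


def detect_outliers_dataset(records: pd.DataFrame,
                            cutoff: float = OUTLIER_CUTOFF,
                            constant: float = MODIFIED_Z_CONSTANT) -> list[QualityFlag]:
    """Run detect_outliers within each district-service-calendar-year."""
    df = records[["district_id", "period", "service", "value"]].copy()
    df["year"] = df["period"] // 100
    flags: list[QualityFlag] = []
    for (d, s, _y), grp in df.groupby(["district_id", "service", "year"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if np.count_nonzero(~np.isnan(vals)) < 2:
            continue
        flags.extend(detect_outliers(vals, district_id=d, service=s,
                                     periods=grp["period"].to_numpy(),
                                     cutoff=cutoff, constant=constant))
    return flags


def flag_low_completeness(records: pd.DataFrame,
                          low: float = LOW_COMPLETENESS,
                          moderate: float = MODERATE_COMPLETENESS) -> list[QualityFlag]:
    """One flag per district-month-service with completeness strictly < low.

    The moderate band (c <= moderate) appears in summaries only and is never
    flagged here.
    """
    if not (0.0 < low <= 1.0 and 0.0 < moderate <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    c = io.completeness(records)
    mask = c < low   # strict: c == low is not flagged; NaN never flagged
    return [
        QualityFlag(r.district_id, int(r.period), r.service,
                    "low_completeness", score=float(ci), threshold=low)
        for r, ci in zip(records[mask].itertuples(), c[mask])
    ]


def missing_scan(records: pd.DataFrame,
                 expected_grid: pd.DataFrame | None = None) -> list[QualityFlag]:
    """Flag every absent or null reported count on the expected lattice.

    ``expected_grid`` is a frame with district_id/period/service columns; by
    default the full cross product of the values observed in ``records``.
    """
    key = ["district_id", "period", "service"]
    if expected_grid is None:
        idx = pd.MultiIndex.from_product(
            [sorted(records["district_id"].unique()),
             sorted(records["period"].unique()),
             sorted(records["service"].unique())], names=key)
        expected_grid = idx.to_frame(index=False)
    merged = expected_grid[key].merge(records[key + ["value"]], on=key, how="left")
    holes = merged[merged["value"].isna()]
    return [QualityFlag(r.district_id, int(r.period), r.service, "missing")
            for r in holes.itertuples()]


@dataclass(frozen=True)
class CompletenessSummary:
    """Annual reporting-completeness roll-up for one dataset (country)."""

    year: int
    national_completeness: float          # percent, unrounded
    pct_districts_above_90: float         # percent of districts, unrounded
    n_district_months_below_75: int
    n_districts: int

    @property
    def national_rounded(self) -> int:
        return int(round(self.national_completeness))

    @property
    def pct_districts_rounded(self) -> int:
        return int(round(self.pct_districts_above_90))


def _dedup_reporting(records: pd.DataFrame) -> pd.DataFrame:
    # reporting-form metadata repeats across services within a district-month
    return (records[["district_id", "period", "reports_expected", "reports_actual"]]
            .drop_duplicates(["district_id", "period"]))


def completeness_summary(records: pd.DataFrame, year: int,
                         low: float = LOW_COMPLETENESS,
                         moderate: float = MODERATE_COMPLETENESS) -> CompletenessSummary:
    """Annual summary: national completeness %, % districts > 90%, low count."""
    sub = _dedup_reporting(records[records["period"] // 100 == year])
    if len(sub) == 0:
        raise ValueError(f"no records for year {year}")
    total_exp = int(sub["reports_expected"].sum())
    if total_exp == 0:
        raise ValueError(f"reports_expected all zero in {year}: "
                         "completeness undefined")
    national = 100.0 * sub["reports_actual"].sum() / total_exp

    per_district = sub.groupby("district_id").agg(
        exp=("reports_expected", "sum"), act=("reports_actual", "sum"))
    per_district = per_district[per_district["exp"] > 0]
    annual_c = per_district["act"] / per_district["exp"]
    pct_above = 100.0 * float((annual_c > moderate).mean())

    with np.errstate(invalid="ignore"):
        month_c = sub["reports_actual"] / sub["reports_expected"]
    n_low = int((month_c < low).sum())
    return CompletenessSummary(
        year=int(year),
        national_completeness=float(national),
        pct_districts_above_90=pct_above,
        n_district_months_below_75=n_low,
        n_districts=int(len(per_district)),
    )


def quality_report(records: pd.DataFrame) -> pd.DataFrame:
    """One row per year with the completeness / missing / outlier summary."""
    years = sorted(set(int(p) // 100 for p in records["period"].unique()))
    n_outliers = flags_to_frame(detect_outliers_dataset(records))
    n_missing = flags_to_frame(missing_scan(records))
    rows = []
    for y in years:
        cs = completeness_summary(records, y)
        in_year = records["period"] // 100 == y
        n_cells = int(in_year.sum())
        rows.append({
            "year": y,
            "national_completeness_pct": round(cs.national_completeness, 1),
            "pct_districts_above_90": round(cs.pct_districts_above_90, 1),
            "n_district_months_below_75": cs.n_district_months_below_75,
            "n_missing": 0 if n_missing.empty else
                int((n_missing["period"] // 100 == y).sum()),
            "n_outliers": 0 if n_outliers.empty else
                int((n_outliers["period"] // 100 == y).sum()),
            "n_cells": n_cells,
        })
    return pd.DataFrame(rows)
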