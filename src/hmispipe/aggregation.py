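"""Bottom-up aggregation and the median/mean margins used in report tables.

National, region and area-type summaries are sums of curated district
counts, so any partition of districts conserves the national total.  Report
margins use a gap-skipping median (empty cells denote data issues and are
skipped, never zero-filled) with the even-cardinality midpoint convention,
and values are displayed rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

STRATA = ("national", "region", "area_type")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention; numpy rounds half-even)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def column_median(values) -> float:
    """Gap-skipping median; even cardinality takes the midpoint.

    Raises ValueError when no non-missing value remains.  Returns the
    unrounded value; use :func:`round_half_away` for display.
    """
    x = np.asarray(pd.Series(values, dtype=float))
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("median undefined: all values missing")
    x = np.sort(x)
    mid = x.size // 2
    if x.size % 2:
        return float(x[mid])
    return float((x[mid - 1] + x[mid]) / 2.0)


def column_mean(values) -> float:
    """Gap-skipping arithmetic mean (unrounded)."""
    x = np.asarray(pd.Series(values, dtype=float))
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("mean undefined: all values missing")
    return float(x.mean())


def rollup(curated: pd.DataFrame, level: str = "national",
           value_col: str = "adjusted_value") -> pd.DataFrame:
    """Sum curated district counts over a partition.

    ``level`` is "national", "region" or "area_type".  Returns a frame with
    columns stratum, service, period, count.
    """
    if level not in STRATA:
        raise ValueError(f"unknown aggregation level {level!r}; "
                         f"expected one of {STRATA}")
    df = curated
    if level == "area_type":
        from .io import AREA_TYPES
        bad = df[~df["area_type"].isin(AREA_TYPES)]
        if len(bad):
            raise ValueError(
                "unknown area_type for district(s): "
                + ", ".join(sorted(bad["district_id"].unique())))
    if level == "national":
        key = pd.Series("national", index=df.index, name="stratum")
    else:
        key = df[level].rename("stratum")
    out = (df.groupby([key, "service", "period"], observed=True)[value_col]
             .sum(min_count=1)
             .rename("count")
             .reset_index())
    return out


def margin_table(grid: pd.DataFrame, group_col: str = "group",
                 groups: tuple = ("West Africa", "Eastern Africa")) -> pd.DataFrame:
    """Append per-group and overall median rows to a country x service grid.

    ``grid`` has one row per country, a ``group_col`` column and one column
    per service (NaN = empty cell).  Margin labels follow the report
    convention: "Median (<group>)" per group plus an overall "Median".
    Row order of the input never changes the margins.
    """
    service_cols = [c for c in grid.columns
                    if c not in (group_col, "country", "median")]
    rows = []
    for g in groups:
        sub = grid[grid[group_col] == g]
        rows.append({"country": f"Median ({g})", group_col: g,
                     **{c: column_median(sub[c]) for c in service_cols
                        if sub[c].notna().any()}})
    rows.append({"country": "Median", group_col: "",
                 **{c: column_median(grid[c]) for c in service_cols
                    if grid[c].notna().any()}})
    return pd.DataFrame(rows)


def country_medians(grid: pd.DataFrame, group_col: str = "group") -> pd.Series:
    """Per-country median across the service columns (gap-skipping)."""
    service_cols = [c for c in grid.columns
                    if c not in (group_col, "country", "median")]
    return grid.apply(
        lambda r: column_median(r[service_cols]), axis=1).set_axis(
            grid["country"])


def build_summary_tables(estimates: pd.DataFrame | None = None,
                         quality_summaries: pd.DataFrame | None = None,
                         strata_estimates: pd.DataFrame | None = None) -> dict:
    """Assemble the report bundle tables from pipeline outputs.

    * ``estimates``: grid of percent changes (rows = countries or strata,
      one column per service) -> margins appended;
    * ``quality_summaries``: per country-year completeness rows, passed
      through;
    * ``strata_estimates``: long frame (service, stratum, pct_change) ->
      per-service urban/rural medians (mixed areas not included).
    """
    tables: dict[str, pd.DataFrame] = {}
    if estimates is not None:
        if len(estimates) == 0:
            tables["estimates"] = estimates
        else:
            margins = margin_table(estimates)
            tables["estimates"] = pd.concat([estimates, margins],
                                            ignore_index=True)
    if quality_summaries is not None:
        tables["quality"] = quality_summaries.copy()
    if strata_estimates is not None:
        sub = strata_estimates[strata_estimates["stratum"].isin(
            ["urban", "rural"])]
        if len(sub):
            tables["area_medians"] = (
                sub.groupby(["service", "stratum"])["pct_change"]
                   .apply(column_median).rename("median_pct_change")
                   .reset_index())
        else:
            tables["area_medians"] = pd.DataFrame(
                columns=["service", "stratum", "median_pct_change"])
    return tables
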