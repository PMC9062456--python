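"""OWID-dialect COVID case/stringency ingestion and pooled association fits.

``load_owid`` reads the daily per-country CSV (columns: location, date,
new_cases, stringency_index, population), forward-filling stringency gaps of
up to 7 days.  ``monthly_metrics`` reduces the series to monthly mean
stringency, monthly new cases and cumulative 2020 incidence per 100 000.
``fit_association`` regresses monthly percent change in utilisation on
cases (per 1000), stringency index, population (per 100 000) and population
density with a country random intercept, one fit per service.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

OWID_COLUMNS = ["location", "date", "new_cases", "stringency_index", "population"]
FFILL_LIMIT_DAYS = 7

COVARIATES = ("new_cases_1000", "stringency_index", "population_100k",
              "population_density")


def load_owid(path_or_buffer) -> pd.DataFrame:
    """Parse an OWID-dialect CSV into a tidy daily series.

    Negative case counts (reporting corrections) are clamped to missing with
    a warning.  Stringency gaps are forward-filled per country for at most
    7 days; longer gaps stay missing.
    """
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in OWID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"OWID csv is missing columns: {missing}")
    df = df[OWID_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")

    dup = df.duplicated(["location", "date"])
    if dup.any():
        raise ValueError("duplicate (location, date) rows in OWID csv")

    neg = df["new_cases"] < 0
    if neg.any():
        warnings.warn(f"{int(neg.sum())} negative new_cases values set to missing")
        df.loc[neg, "new_cases"] = np.nan

    bad = ~df["stringency_index"].between(0, 100) & df["stringency_index"].notna()
    if bad.any():
        raise ValueError("stringency_index outside [0, 100]")

    df = df.sort_values(["location", "date"]).reset_index(drop=True)
    df["stringency_index"] = (
        df.groupby("location")["stringency_index"]
          .transform(lambda s: s.ffill(limit=FFILL_LIMIT_DAYS)))
    return df


def monthly_metrics(series: pd.DataFrame,
                    window: tuple[int, int] = (202003, 202012)) -> pd.DataFrame:
    """Per-country monthly metrics over the window, plus 2020 cumulative incidence.

    Returns one row per country-month: mean_stringency, new_cases (monthly
    total), cumulative_cases_per_100k (whole of 2020, repeated per row).
    """
    df = series.copy()
    df["period"] = df["date"].dt.year * 100 + df["date"].dt.month
    lo, hi = window
    pop = df.groupby("location")["population"].first()
    if (pop <= 0).any() or pop.isna().any():
        bad = pop.index[(pop <= 0) | pop.isna()].tolist()
        raise ValueError(f"nonpositive or missing population for {bad}")

    cum = (df[df["period"] // 100 == 2020]
           .groupby("location")["new_cases"].sum(min_count=1))
    cum_per_100k = 100_000.0 * cum / pop

    sub = df[(df["period"] >= lo) & (df["period"] <= hi)]
    out = (sub.groupby(["location", "period"])
              .agg(mean_stringency=("stringency_index", "mean"),
                   new_cases=("new_cases", lambda s: s.sum(min_count=1)))
              .reset_index())
    out["cumulative_cases_per_100k"] = out["location"].map(cum_per_100k)
    out["population"] = out["location"].map(pop)
    return out


@dataclass(frozen=True)
class AssociationResult:
    service: str
    coefficients: dict           # covariate -> coefficient
    std_errors: dict
    p_values: dict
    n_obs: int
    model_variant: str

    def stars(self, covariate: str) -> str:
        p = self.p_values[covariate]
        if p < 0.001:
            return "***"
        if p < 0.05:
            return "*"
        return ""


def association_table(results) -> pd.DataFrame:
    """Report-style table: one column per service, one row per covariate."""
    rows = []
    for cov in COVARIATES:
        row = {"variable": cov}
        for r in results:
            if cov in r.coefficients:
                row[r.service] = f"{r.coefficients[cov]:.3f}{r.stars(cov)}"
        rows.append(row)
    return pd.DataFrame(rows)


def fit_association(panel: pd.DataFrame, service: str | None = None,
                    outcome: str = "pct_change") -> list[AssociationResult]:
    """Country-random-intercept regression of monthly percent change.

    ``panel`` columns: country, period, service, pct_change, new_cases,
    stringency, population, population_density.  Covariate scalings follow
    the report convention: cases per 1000, population per 100 000.
    Falls back to pooled OLS when the mixed fit degenerates (e.g. zero
    residual noise).
    """
    df = panel.copy()
    df["new_cases_1000"] = df["new_cases"] / 1000.0
    df["stringency_index"] = df["stringency"]
    df["population_100k"] = df["population"] / 100_000.0

    services = [service] if service else sorted(df["service"].unique())
    results = []
    for svc in services:
        sub = df[df["service"] == svc].dropna(
            subset=[outcome, *COVARIATES]).reset_index(drop=True)
        if sub["country"].nunique() < 2:
            raise ValueError(f"{svc}: need >= 2 countries")
        if sub.groupby("country")["period"].nunique().min() < 2:
            warnings.warn(f"{svc}: some countries contribute a single month")

        degenerate = [c for c in COVARIATES if sub[c].nunique() <= 1]
        if degenerate:
            raise ValueError(
                f"{svc}: zero-variance covariates: {', '.join(degenerate)}")

        formula = f"{outcome} ~ " + " + ".join(COVARIATES)
        result, variant = None, "mixed_intercept"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, sub, groups=sub["country"]).fit(
                    reml=True)
            ok = fit.converged and np.all(
                np.isfinite([fit.params[c] for c in COVARIATES]))
            if ok:
                result = fit
        except Exception as exc:
            logger.warning("%s: mixed fit failed (%s); using OLS", svc, exc)
        if result is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = smf.ols(formula, sub).fit()
            variant = "ols"

        results.append(AssociationResult(
            service=svc,
            coefficients={c: float(result.params[c]) for c in COVARIATES},
            std_errors={c: float(result.bse[c]) for c in COVARIATES},
            p_values={c: float(result.pvalues[c]) for c in COVARIATES},
            n_obs=len(sub),
            model_variant=variant,
        ))
    return results
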