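"""Mixed-effects estimation of COVID-period changes in service utilisation.

District-month counts are regressed on a linear time trend, calendar-month
dummies, district population, area-type and region dummies, plus either one
indicator per COVID month (monthly mode) or a single whole-period indicator
(period mode).  Districts carry a random intercept and a random time slope.

A COVID coefficient is converted to a percent change by dividing it by the
counterfactual mean — the average fixed-effects prediction over the COVID
rows with all COVID indicators forced to zero.  CI endpoints scale the
coefficient's normal-approximation CI by the same denominator (the
denominator is treated as fixed).

Fallback hierarchy on non-convergence or non-finite standard errors:
random intercept + slope -> random intercept -> pooled OLS, each logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .periods import months_between, period_range

logger = logging.getLogger(__name__)

COVID_START = 202003
COVID_END = 202012
Z95 = 1.96

REFERENCE_MONTH = 1        # January
REFERENCE_AREA = "urban"   # area dummies relative to urban


@dataclass(frozen=True)
class DisruptionEstimate:
    service: str
    stratum: str
    period: str                  # "YYYYMM" or "YYYYMM-YYYYMM"
    coefficient: float
    se: float
    expected_mean: float         # counterfactual mean count
    pct_change: float
    ci_low: float
    ci_high: float
    model_variant: str
    alt_pct_change: float | None = None   # district-aggregated cross-check


def estimates_to_frame(estimates) -> pd.DataFrame:
    cols = ["service", "stratum", "period", "pct_change", "ci_low", "ci_high",
            "coefficient", "se", "expected_mean", "model_variant",
            "alt_pct_change"]
    if not estimates:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in estimates])[cols]


def covid_columns(mode: str, covid_start: int = COVID_START,
                  covid_end: int = COVID_END) -> list[str]:
    if mode == "period":
        return ["covid_period"]
    if mode == "monthly":
        return [f"covid_{p}" for p in period_range(covid_start, covid_end)]
    raise ValueError(f"mode must be 'monthly' or 'period', got {mode!r}")


def build_frame(curated: pd.DataFrame, service: str,
                covid_start: int = COVID_START, covid_end: int = COVID_END,
                mode: str = "monthly", min_pre_months: int = 24,
                value_col: str = "adjusted_value") -> pd.DataFrame:
    """Model frame for one service: outcome, covariates, COVID indicators."""
    df = curated[curated["service"] == service].copy()
    if len(df) == 0:
        raise ValueError(f"no curated records for service {service!r}")
    df = df.dropna(subset=[value_col])
    start = int(df["period"].min())
    pre = df[df["period"] < covid_start]["period"].nunique()
    if pre == 0:
        raise ValueError("all data fall in the COVID window; cannot model")
    if pre < min_pre_months:
        warnings.warn(f"only {pre} pre-COVID months available "
                      f"(recommended >= {min_pre_months})")

    frame = pd.DataFrame({
        "district": df["district_id"].to_numpy(),
        "y": df[value_col].to_numpy(dtype=float),
        "time": [months_between(start, p) for p in df["period"]],
        "month": (df["period"] % 100).to_numpy(),
        "pop": df["population"].to_numpy(dtype=float) / 1e5,
        "area": df["area_type"].to_numpy(),
        "region": df["region"].to_numpy(),
        "period": df["period"].to_numpy(),
    })
    for col in covid_columns(mode, covid_start, covid_end):
        if col == "covid_period":
            frame[col] = ((frame["period"] >= covid_start)
                          & (frame["period"] <= covid_end)).astype(float)
        else:
            frame[col] = (frame["period"] == int(col.split("_")[1])).astype(float)
    frame.attrs["mode"] = mode
    frame.attrs["service"] = service
    frame.attrs["covid_cols"] = covid_columns(mode, covid_start, covid_end)
    return frame


@dataclass
class DisruptionFit:
    result: object               # statsmodels results wrapper
    formula: str
    covid_cols: list
    variant: str                 # "mixed_slope" | "mixed_intercept" | "ols"

    @property
    def params(self):
        return self.result.params

    @property
    def bse(self):
        return self.result.bse

    def predict_fixed(self, frame: pd.DataFrame) -> np.ndarray:
        # fixed-effects (population-average) prediction for both model kinds
        return np.asarray(self.result.predict(exog=frame))


def _formula(frame: pd.DataFrame, covid_cols) -> str:
    terms = ["time", f"C(month, Treatment({REFERENCE_MONTH}))"]
    if frame["pop"].nunique() > 1:
        terms.append("pop")
    if frame["area"].nunique() > 1:
        ref = (f", Treatment('{REFERENCE_AREA}')"
               if REFERENCE_AREA in set(frame["area"]) else "")
        terms.append(f"C(area{ref})")
    else:
        logger.info("single area level; dropping area term")
    if frame["region"].nunique() > 1:
        terms.append("C(region)")   # reference = first level alphabetically
    else:
        logger.info("single region level; dropping region term")
    terms += list(covid_cols)
    return "y ~ " + " + ".join(terms)


def _fixed_ok(result, covid_cols) -> bool:
    try:
        bse = result.bse
    except Exception:
        return False
    vals = [result.params.get(c, np.nan) for c in covid_cols]
    ses = [bse.get(c, np.nan) for c in covid_cols]
    return bool(np.all(np.isfinite(vals)) and np.all(np.isfinite(ses))
                and np.all(np.asarray(ses) > 0))


def fit_mixed_model(frame: pd.DataFrame, covid_cols=None) -> DisruptionFit:
    """Fit the disruption model with the documented fallback hierarchy."""
    covid_cols = list(covid_cols or frame.attrs.get("covid_cols") or [])
    if not covid_cols:
        raise ValueError("no COVID indicator columns supplied")
    if frame["district"].nunique() < 2:
        raise ValueError("need >= 2 districts for a mixed model")
    formula = _formula(frame, covid_cols)

    for re_formula, variant in (("~time", "mixed_slope"),
                                (None, "mixed_intercept")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, frame, groups=frame["district"],
                                    re_formula=re_formula)
                result = model.fit(reml=True)
            if result.converged and _fixed_ok(result, covid_cols):
                return DisruptionFit(result, formula, covid_cols, variant)
            logger.warning("variant %s did not converge cleanly; falling back",
                           variant)
        except Exception as exc:   # singular designs raise LinAlgError etc.
            logger.warning("variant %s failed (%s); falling back", variant, exc)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = smf.ols(formula, frame).fit()
    logger.warning("mixed model failed; using pooled OLS")
    return DisruptionFit(result, formula, covid_cols, "ols")


def _counterfactual(fit: DisruptionFit, rows: pd.DataFrame) -> np.ndarray:
    cf = rows.copy()
    for c in fit.covid_cols:
        cf[c] = 0.0
    return fit.predict_fixed(cf)


def percent_change(fit: DisruptionFit, frame: pd.DataFrame,
                   stratum: str = "national",
                   service: str | None = None) -> list[DisruptionEstimate]:
    """Convert COVID coefficients into percent-change estimates.

    Monthly mode yields one estimate per COVID month; period mode a single
    whole-period estimate.  ``stratum`` only labels the output; pass a
    pre-filtered frame for stratified estimates.
    """
    service = service or frame.attrs.get("service", "")
    estimates = []
    for col in fit.covid_cols:
        rows = frame[frame[col] == 1.0]
        if len(rows) == 0:
            logger.warning("no rows active for %s; skipping", col)
            continue
        cf = _counterfactual(fit, rows)
        mean_cf = float(np.mean(cf))
        if mean_cf <= 0:
            raise ValueError(
                f"counterfactual mean <= 0 for {col}; percent change undefined")
        beta = float(fit.params[col])
        se = float(fit.bse[col])
        pct = 100.0 * beta / mean_cf
        lo = 100.0 * (beta - Z95 * se) / mean_cf
        hi = 100.0 * (beta + Z95 * se) / mean_cf

        # cross-check: aggregate the predicted relative change by district
        per_d = rows.assign(_cf=cf).groupby("district")["_cf"].mean()
        alt = float(np.mean(100.0 * beta / per_d[per_d > 0]))

        if col == "covid_period":
            label = f"{int(rows['period'].min())}-{int(rows['period'].max())}"
        else:
            label = col.split("_")[1]
        estimates.append(DisruptionEstimate(
            service=service, stratum=stratum, period=label,
            coefficient=beta, se=se, expected_mean=mean_cf,
            pct_change=pct, ci_low=lo, ci_high=hi,
            model_variant=fit.variant, alt_pct_change=alt))
    return estimates


def estimate_service(curated: pd.DataFrame, service: str,
                     mode: str = "period", covid_start: int = COVID_START,
                     covid_end: int = COVID_END) -> list[DisruptionEstimate]:
    """Build frame, fit, and convert — the whole chain for one service."""
    frame = build_frame(curated, service, covid_start, covid_end, mode)
    fit = fit_mixed_model(frame)
    return percent_change(fit, frame, service=service)


def stratified_estimates(curated: pd.DataFrame, service: str,
                         strata_col: str = "area_type", mode: str = "period",
                         covid_start: int = COVID_START,
                         covid_end: int = COVID_END) -> list[DisruptionEstimate]:
    """Refit the model within each stratum (e.g. urban/rural/mixed)."""
    out = []
    for stratum, sub in curated[curated["service"] == service].groupby(strata_col):
        if sub["district_id"].nunique() < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 districts; skipped")
            continue
        frame = build_frame(sub, service, covid_start, covid_end, mode)
        fit = fit_mixed_model(frame)
        out.extend(percent_change(fit, frame, stratum=str(stratum),
                                  service=service))
    return out
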