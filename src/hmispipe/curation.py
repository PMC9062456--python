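"""Curated dataset construction: adjust, impute, exclude — with an audit log.

Order of operations in :func:`curate`:

1. flags (missing / outlier / low-completeness) are computed on the raw data;
2. flagged cells are imputed with the calendar-year median of the clean
   cells of the same district-service series (true-zero overrides stay 0);
3. remaining cells are adjusted for incomplete reporting,
   ``adjusted = count * (1 + (1/c - 1) * k)`` with a per-service factor k;
4. configured exclusion windows are applied.

Imputed values stand in for a fully-reported month and are not additionally
adjusted.  Every modified cell gets exactly one log entry; replaying the log
against the raw dataset reproduces the curated dataset exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, quality
from .periods import check_period

LOG_COLUMNS = ["district_id", "period", "service", "action",
               "original", "replacement", "params"]

ACTIONS = ("adjusted", "imputed_low_completeness", "imputed_missing",
           "imputed_outlier", "excluded", "kept_zero")

DEFAULT_K = 0.25


@dataclass(frozen=True)
class ExclusionWindow:
    """Period window to drop, at country/region/district scope."""

    scope: str                 # "country" | "region" | "district"
    target: str | None         # region or district id; None for country
    start: int
    end: int
    reason: str = ""

    def __post_init__(self):
        if self.scope not in ("country", "region", "district"):
            raise ValueError(f"unknown exclusion scope {self.scope!r}")
        check_period(self.start)
        check_period(self.end)
        if self.start > self.end:
            raise ValueError("exclusion window start after end")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = (df["period"] >= self.start) & (df["period"] <= self.end)
        if self.scope == "region":
            m &= df["region"] == self.target
        elif self.scope == "district":
            m &= df["district_id"] == self.target
        return m


@dataclass(frozen=True)
class AdjustmentPolicy:
    """Curation parameters: adjustment factors, thresholds, overrides."""

    k_by_service: dict = field(default_factory=dict)
    default_k: float = DEFAULT_K
    low_completeness_threshold: float = quality.LOW_COMPLETENESS
    outlier_cutoff: float = quality.OUTLIER_CUTOFF
    true_zero_overrides: frozenset = frozenset()   # {(district, period, service)}
    exclusion_windows: tuple = ()

    def __post_init__(self):
        for s, k in self.k_by_service.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"adjustment factor for {s} outside [0,1]: {k}")
        if not 0.0 <= self.default_k <= 1.0:
            raise ValueError(f"default_k outside [0,1]: {self.default_k}")

    def k_for(self, service: str) -> float:
        return self.k_by_service.get(service, self.default_k)


def adjust_for_completeness(count, c, k):
    """Scale a reported count up for non-reporting facilities.

    ``adjusted = count * (1 + (1/c - 1) * k)`` — k = 0 assumes non-reporting
    facilities delivered nothing, k = 1 that they delivered like reporters
    (count / c).  Monotone and continuous in k; never below ``count``.
    """
    count = np.asarray(count, dtype=float)
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("completeness must lie in (0, 1]; impute c == 0 cells")
    if np.any((k < 0) | (k > 1)):
        raise ValueError("adjustment factor k must lie in [0, 1]")
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    out = count * (1.0 + (1.0 / c - 1.0) * k)
    return float(out) if out.ndim == 0 else out


def impute_calendar_median(series, flagged, true_zero=None):
    """Replace flagged cells with the median of the year's clean cells.

    ``series`` is one district-service calendar year (any length), ``flagged``
    a boolean mask, ``true_zero`` an optional mask of cells to keep at 0.
    Returns (imputed series, actions list aligned with the series, median).
    Raises LookupError when no clean cell remains.
    """
    x = np.asarray(series, dtype=float)
    flagged = np.asarray(flagged, dtype=bool)
    true_zero = (np.zeros(len(x), dtype=bool) if true_zero is None
                 else np.asarray(true_zero, dtype=bool))
    clean = ~flagged & ~np.isnan(x)
    if not clean.any():
        raise LookupError("no clean cells in calendar year: cannot impute")
    med = float(np.median(x[clean]))
    out = x.copy()
    actions: list[str | None] = [None] * len(x)
    for i in range(len(x)):
        if not flagged[i]:
            continue
        if true_zero[i]:
            out[i] = 0.0
            actions[i] = "kept_zero"
        else:
            out[i] = med
            actions[i] = "imputed"
    return out, actions, med


def apply_exclusions(df: pd.DataFrame, windows) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records inside the windows; returns (kept, log entries).

    Overlapping windows are applied as a union: one log entry per record,
    carrying the first matching window's reason.
    """
    if len(df) == 0 or not windows:
        return df.copy(), pd.DataFrame(columns=LOG_COLUMNS)
    dropped = pd.Series(False, index=df.index)
    reason = pd.Series("", index=df.index, dtype=object)
    for w in windows:
        m = w.mask(df)
        if not m.any():
            warnings.warn(f"exclusion window {w} matches no records")
        new = m & ~dropped
        reason[new] = w.reason or f"{w.scope}:{w.start}-{w.end}"
        dropped |= m
    log = pd.DataFrame({
        "district_id": df.loc[dropped, "district_id"],
        "period": df.loc[dropped, "period"],
        "service": df.loc[dropped, "service"],
        "action": "excluded",
        "original": df.loc[dropped, "value"],
        "replacement": np.nan,
        "params": reason[dropped],
    })
    return df[~dropped].copy(), log.reset_index(drop=True)


def curate(dataset: pd.DataFrame,
           policy: AdjustmentPolicy | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the curated dataset and its log.

    Returns (curated frame with an ``adjusted_value`` column, log frame with
    one row per modified cell).  Deterministic; replaying the log on the raw
    dataset reproduces the curated dataset (see :func:`replay_log`).
    """
    policy = policy or AdjustmentPolicy()
    df = dataset.copy().reset_index(drop=True)

    c = io.completeness(df).to_numpy()
    missing = df["value"].isna().to_numpy()
    low = np.zeros(len(df), dtype=bool)
    with np.errstate(invalid="ignore"):
        low = (c < policy.low_completeness_threshold) | np.isnan(c) | (c == 0)
    low &= ~missing

    outlier = np.zeros(len(df), dtype=bool)
    out_flags = quality.detect_outliers_dataset(df, cutoff=policy.outlier_cutoff)
    if out_flags:
        keyed = {(f.district_id, f.period, f.service) for f in out_flags}
        keys = list(zip(df["district_id"], df["period"], df["service"]))
        outlier = np.array([k in keyed for k in keys])
    outlier &= ~missing

    flagged = missing | low | outlier
    tz = policy.true_zero_overrides
    true_zero = (np.array([(d, p, s) in tz for d, p, s in
                           zip(df["district_id"], df["period"], df["service"])])
                 if tz else np.zeros(len(df), dtype=bool))

    adjusted = df["value"].to_numpy(dtype=float).copy()
    action = np.full(len(df), None, dtype=object)
    params = np.full(len(df), "", dtype=object)

    year = (df["period"] // 100).to_numpy()
    for (_d, _s, _y), grp in df.groupby(["district_id", "service",
                                         df["period"] // 100], sort=False):
        idx = grp.index.to_numpy()
        if not flagged[idx].any():
            continue
        try:
            vals, acts, med = impute_calendar_median(
                adjusted[idx], flagged[idx], true_zero[idx])
        except LookupError:
            warnings.warn(
                f"district {_d} service {_s} year {_y}: every cell flagged; "
                "left missing")
            adjusted[idx] = np.nan
            for i in idx:
                action[i] = _impute_action(missing[i], outlier[i], low[i])
                params[i] = "escalated:no_clean_cells"
            continue
        adjusted[idx] = vals
        for j, i in enumerate(idx):
            if acts[j] == "kept_zero":
                action[i] = "kept_zero"
                params[i] = "true_zero_override"
            elif acts[j] == "imputed":
                action[i] = _impute_action(missing[i], outlier[i], low[i])
                params[i] = f"calendar_median={med}"

    # stage 3: completeness adjustment of untouched cells
    plain = ~flagged
    ks = np.array([policy.k_for(s) for s in df["service"]])
    adjustable = plain & (c > 0) & (c <= 1) & ~np.isnan(adjusted)
    adj = adjust_for_completeness(adjusted[adjustable], c[adjustable],
                                  ks[adjustable])
    changed = adj != adjusted[adjustable]
    sub = np.flatnonzero(adjustable)
    adjusted[sub] = adj
    for i, ch, a in zip(sub, changed, adj):
        if ch:
            action[i] = "adjusted"
            params[i] = f"c={c[i]:.6g},k={ks[i]:.6g}"

    curated = df.copy()
    curated["adjusted_value"] = adjusted

    touched = np.flatnonzero(action != None)  # noqa: E711  (object array)
    log = pd.DataFrame({
        "district_id": curated.loc[touched, "district_id"],
        "period": curated.loc[touched, "period"],
        "service": curated.loc[touched, "service"],
        "action": action[touched],
        "original": df.loc[touched, "value"],
        "replacement": adjusted[touched],
        "params": params[touched],
    }).reset_index(drop=True)

    curated, excl_log = apply_exclusions(curated, policy.exclusion_windows)
    if len(excl_log):
        key = ["district_id", "period", "service"]
        excl_keys = set(map(tuple, excl_log[key].to_numpy()))
        keep = [tuple(r) not in excl_keys for r in log[key].to_numpy()]
        log = pd.concat([log[keep], excl_log], ignore_index=True)
    return curated.reset_index(drop=True), log[LOG_COLUMNS]


def _impute_action(is_missing: bool, is_outlier: bool, is_low: bool) -> str:
    # precedence mirrors flag severity: a missing cell cannot be an outlier
    if is_missing:
        return "imputed_missing"
    if is_outlier:
        return "imputed_outlier"
    return "imputed_low_completeness"


def replay_log(raw: pd.DataFrame, log: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the curated dataset from the raw dataset plus the log."""
    df = raw.copy().reset_index(drop=True)
    df["adjusted_value"] = df["value"].astype(float)
    key = ["district_id", "period", "service"]
    excl = log[log["action"] == "excluded"]
    mods = log[log["action"] != "excluded"]
    if len(mods):
        repl = mods.set_index(key)["replacement"]
        idx = pd.MultiIndex.from_frame(df[key])
        hit = idx.isin(repl.index)
        df.loc[hit, "adjusted_value"] = repl.loc[idx[hit]].to_numpy()
    if len(excl):
        drop = pd.MultiIndex.from_frame(df[key]).isin(
            pd.MultiIndex.from_frame(excl[key]))
        df = df[~drop]
    return df.reset_index(drop=True)
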