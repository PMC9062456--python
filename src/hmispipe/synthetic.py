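"""Synthetic DHIS2-style district-month datasets with known ground truth.

The generator produces monthly service counts per district with log-linear
trend, calendar-month seasonality, district heterogeneity in level and
trend, an optional COVID-period shock, and a facility reporting process
(per-district-month completeness, non-reporting facilities delivering a
configurable fraction ``q`` of the volume of reporting ones).  Missing
values and extreme outliers are injected at configurable rates.

Ground truth is kept in a sidecar frame so every downstream stage
(quality flags, curation, modelling) can be validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io
from .periods import check_period, months_between, period_month, period_range

DEFAULT_SERVICES = (
    "ANC1", "ANC4", "DELIV", "CSEC", "PENTA1",
    "PENTA3", "MEASLES", "OPD", "IPD",
)

# typical district-month volumes; OPD dwarfs the rest
DEFAULT_BASELINES = {
    "ANC1": 400.0, "ANC4": 250.0, "DELIV": 300.0, "CSEC": 30.0,
    "PENTA1": 350.0, "PENTA3": 330.0, "MEASLES": 320.0,
    "OPD": 5000.0, "IPD": 250.0,
}

TRUTH_COLUMNS = ["district_id", "period", "service", "true_count", "true_shock_pct"]

COMPLETENESS_FLOOR = 0.05


def uniform_shock(delta: float, services=DEFAULT_SERVICES,
                  start: int = 202003, end: int = 202012) -> dict:
    """Constant multiplicative shock ``delta`` (e.g. -0.15) over a window."""
    return {s: {p: float(delta) for p in period_range(start, end)}
            for s in services}


def step_rebound_shock(initial: float, final: float = 0.0,
                       services=DEFAULT_SERVICES,
                       start: int = 202003, end: int = 202012) -> dict:
    """Step shock at ``start`` rebounding linearly to ``final`` by ``end``."""
    periods = period_range(start, end)
    n = len(periods)
    deltas = [initial + (final - initial) * i / (n - 1) for i in range(n)] \
        if n > 1 else [initial]
    return {s: dict(zip(periods, deltas)) for s in services}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic scenario.

    ``shock`` maps service -> {period -> relative change} (e.g. -0.2 for a
    20% drop); omitted periods carry no shock.  ``noise`` is one of
    "poisson", "gaussian" (with ``noise_cv``) or "none".
    """

    n_districts: int = 20
    n_facilities_per_district: float = 20.0
    start: int = 201701
    end: int = 202012
    services: tuple = DEFAULT_SERVICES
    baseline_level: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    level_cv: float = 0.3          # district-level dispersion of baselines
    annual_growth: dict = field(default_factory=dict)   # service -> rel/yr
    trend_sd: float = 0.0          # per-district SD around annual growth
    seasonal_factors: dict = field(default_factory=dict)  # service -> 12 floats
    shock: dict = field(default_factory=dict)
    completeness_mean: float = 1.0
    completeness_concentration: float = 50.0
    q_nonreporting: float = 0.25
    outlier_rate: float = 0.0
    missing_rate: float = 0.0
    noise: str = "poisson"
    noise_cv: float = 0.1
    round_counts: bool = True
    n_regions: int = 4
    area_shares: tuple = (0.4, 0.4, 0.2)   # urban, rural, mixed
    population_mean: float = 150_000.0
    population_cv: float = 0.4
    seed: int = 0

    def __post_init__(self):
        check_period(self.start)
        check_period(self.end)
        if self.start > self.end:
            raise ValueError("period range start after end")
        if self.n_districts < 1:
            raise ValueError("n_districts must be positive")
        if self.n_facilities_per_district <= 0:
            raise ValueError("n_facilities_per_district must be positive")
        for name in ("completeness_mean", "q_nonreporting",
                     "outlier_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise family: {self.noise!r}")
        for s, factors in self.seasonal_factors.items():
            if len(factors) != 12:
                raise ValueError(f"seasonal_factors[{s}] needs 12 entries")
            prod = math.prod(factors)
            if abs(prod - 1.0) > 1e-9:
                raise ValueError(
                    f"seasonal_factors[{s}] must multiply to 1 (got {prod})")
        for s, window in self.shock.items():
            for p, d in window.items():
                check_period(p)
                if d <= -1.0:
                    raise ValueError(f"shock multiplier {d} at {s}/{p} <= -1")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent substreams so truth/district/reporting draws do not interact
    return np.random.default_rng([int(config.seed), stream])


def district_table(config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic district attributes: region, area type, population, size."""
    rng = _rng(config, 0)
    n = config.n_districts
    ids = [f"D{i + 1:03d}" for i in range(n)]
    regions = [f"R{i % config.n_regions + 1}" for i in range(n)]
    shares = np.asarray(config.area_shares, dtype=float)
    shares = shares / shares.sum()
    areas = rng.choice(np.array(io.AREA_TYPES), size=n, p=shares)
    sigma = math.sqrt(math.log(1 + config.population_cv ** 2))
    pop = np.round(config.population_mean
                   * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n)))
    n_fac = np.maximum(1, rng.poisson(config.n_facilities_per_district, size=n))
    return pd.DataFrame({
        "district_id": ids, "region": regions, "area_type": areas,
        "population": pop.astype(int), "n_facilities": n_fac.astype(int),
    })


def expected_count(config: ScenarioConfig, district_level: float,
                   district_growth: float, service: str, period: int) -> float:
    """Mean count before noise: level x trend x seasonality x (1 + shock)."""
    t = months_between(config.start, period)
    seasonal = config.seasonal_factors.get(service)
    s = seasonal[period_month(period) - 1] if seasonal else 1.0
    delta = config.shock.get(service, {}).get(period, 0.0)
    return district_level * (1.0 + district_growth) ** (t / 12.0) * s * (1.0 + delta)


def generate_truth(config: ScenarioConfig) -> pd.DataFrame:
    """Ground-truth counts per district x period x service.

    Columns: district_id, period, service, true_count, true_shock_pct.
    Deterministic under (config, seed).
    """
    districts = district_table(config)
    rng = _rng(config, 1)
    periods = period_range(config.start, config.end)
    n_d, n_p = len(districts), len(periods)

    sigma = math.sqrt(math.log(1 + config.level_cv ** 2)) if config.level_cv else 0.0
    frames = []
    for service in config.services:
        base = config.baseline_level.get(service, DEFAULT_BASELINES.get(service))
        if base is None:
            raise ValueError(f"no baseline level configured for {service!r}")
        growth = config.annual_growth.get(service, 0.0)
        level_mult = (np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n_d))
                      if sigma else np.ones(n_d))
        d_growth = growth + (rng.normal(0.0, config.trend_sd, size=n_d)
                             if config.trend_sd else np.zeros(n_d))
        mu = np.empty((n_d, n_p))
        shock_pct = np.zeros(n_p)
        window = config.shock.get(service, {})
        for j, p in enumerate(periods):
            shock_pct[j] = 100.0 * window.get(p, 0.0)
            for i in range(n_d):
                mu[i, j] = expected_count(
                    config, base * level_mult[i], d_growth[i], service, p)
        if config.noise == "poisson":
            counts = rng.poisson(mu).astype(float)
        elif config.noise == "gaussian":
            counts = np.maximum(
                0.0, np.round(rng.normal(mu, config.noise_cv * mu)))
        else:
            counts = mu
        frames.append(pd.DataFrame({
            "district_id": np.repeat(districts["district_id"].to_numpy(), n_p),
            "period": np.tile(periods, n_d),
            "service": service,
            "true_count": counts.ravel(),
            "true_shock_pct": np.tile(shock_pct, n_d),
        }))
    return pd.concat(frames, ignore_index=True)[TRUTH_COLUMNS]


def apply_reporting(truth: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Push truth through the facility reporting process.

    Completeness c is drawn per district-month (shared by all services, as
    with a single monthly reporting form) from a Beta with the configured
    mean/concentration, floored at 0.05.  A district-month reports
    ``reported = true x c / (c + (1-c) q)`` where q is the relative volume
    of a non-reporting facility.  Injected missing records carry no value;
    injected outliers are multiplied by a factor in [10, 50].
    """
    districts = district_table(config).set_index("district_id")
    rng = _rng(config, 2)

    periods = sorted(truth["period"].unique())
    d_ids = list(districts.index)
    m, conc = config.completeness_mean, config.completeness_concentration
    c_map = {}
    for d in d_ids:
        n_fac = int(districts.loc[d, "n_facilities"])
        for p in periods:
            if m >= 1.0:
                c_raw = 1.0
            else:
                c_raw = rng.beta(m * conc, (1.0 - m) * conc)
            c_raw = max(c_raw, COMPLETENESS_FLOOR)
            actual = int(np.clip(round(c_raw * n_fac), 1, n_fac))
            c_map[(d, p)] = (n_fac, actual)

    df = truth.merge(districts[["region", "area_type", "population"]],
                     left_on="district_id", right_index=True, how="left")
    expected = np.empty(len(df), dtype=int)
    actual = np.empty(len(df), dtype=int)
    for i, (d, p) in enumerate(zip(df["district_id"], df["period"])):
        expected[i], actual[i] = c_map[(d, p)]
    c = actual / expected
    q = config.q_nonreporting
    reported = df["true_count"].to_numpy() * c / (c + (1.0 - c) * q)
    if config.round_counts:
        reported = np.round(reported)

    value = reported.astype(float)
    if config.outlier_rate > 0:
        hit = rng.random(len(df)) < config.outlier_rate
        factors = rng.uniform(10.0, 50.0, size=len(df))
        value = np.where(hit, np.round(value * factors), value)
    if config.missing_rate > 0:
        gone = rng.random(len(df)) < config.missing_rate
        value = np.where(gone, np.nan, value)

    out = pd.DataFrame({
        "district_id": df["district_id"],
        "region": df["region"],
        "area_type": df["area_type"],
        "population": df["population"],
        "period": df["period"],
        "service": df["service"],
        "value": value,
        "reports_expected": expected,
        "reports_actual": actual,
    })
    return out[io.SCHEMA]


def simulate(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (service records, truth sidecar) for one scenario."""
    truth = generate_truth(config)
    records = apply_reporting(truth, config)
    return records, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"district_id": str, "service": str})
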