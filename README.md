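# hmispipe

District-level routine health facility (HMIS/DHIS2-style) data pipeline:

* **`hmispipe.synthetic`** — generator for DHIS2-like district-month service
  counts with known ground truth: log-linear trend, calendar-month
  seasonality, district heterogeneity in level and trend, a facility
  reporting process (per-district-month completeness, non-reporting
  facilities delivering a fraction *q* of a reporter's volume), injected
  missing values and extreme outliers, and a COVID-period shock
  (step + rebound) from March 2020.
* **`hmispipe.quality`** — data-quality assessment: reporting completeness
  summaries (national %, % districts > 90%, district-months < 75%), missing
  value scan over the full district × period × service lattice, and extreme
  outlier detection via the modified Z-score (0.6745 · |x − median| / MAD,
  cutoff 5, computed within each district-service calendar year, with a
  mean-absolute-deviation fallback when the MAD is zero).
* **`hmispipe.curation`** — the curated dataset: calendar-year-median
  imputation of missing / outlier / low-completeness (< 75%) cells
  (true-zero overrides respected), completeness adjustment
  `adjusted = count × (1 + (1/c − 1) k)` with per-service factors
  (default k = 0.25), configurable exclusion windows, and a replayable audit
  log (raw data + log reconstructs the curated dataset exactly).
* **`hmispipe.aggregation`** — bottom-up national / region / urban-rural
  roll-ups (partition sums conserve the national total) and the
  gap-skipping median / mean margins used in the report tables, with
  half-away-from-zero display rounding.
* **`hmispipe.model`** — mixed-effects estimation of COVID-period changes:
  district-month counts regressed on time trend, calendar-month dummies,
  population, area-type and region dummies, plus per-month or whole-period
  COVID indicators; random intercept + time slope by district (REML), with
  a documented fallback hierarchy (random slope → random intercept → pooled
  OLS). Coefficients are converted to percent change against the
  counterfactual (COVID indicators zeroed) predicted mean, with ±1.96 SE
  intervals scaled by the same denominator.
* **`hmispipe.stringency`** — OWID-dialect daily case/stringency ingestion
  (≤ 7-day forward fill), monthly metrics (mean stringency, monthly cases,
  cumulative 2020 incidence per 100k), and per-service country-random-
  intercept regressions of monthly percent change on cases (per 1000),
  stringency, population (per 100k) and density.
* **`hmispipe.cli`** — configuration-driven orchestration with a run
  manifest; reruns with the same config + seed are byte-identical.
* **`hmispipe.reference`** — published per-country summary values shipped
  as package data, used as worked examples for the aggregation margins.

## CLI

```bash
hmispipe simulate  --config config.yaml --seed 1 --out out/   # synthetic data + truth sidecar
hmispipe validate  out/simulated.csv                          # schema/consistency report
hmispipe quality   out/simulated.csv --out quality.csv
hmispipe curate    out/simulated.csv --config config.yaml --out out/
hmispipe estimate  out/curated.csv --mode period
hmispipe associate panel.csv --out association.csv
hmispipe run-all   --config config.yaml --seed 1 --out out/   # full pipeline + manifest
```

Minimal `config.yaml`:

```yaml
scenario:
  n_districts: 60
  start: 201701
  end: 202012
  services: [ANC1, ANC4, DELIV, CSEC, PENTA1, PENTA3, MEASLES, OPD, IPD]
  completeness_mean: 0.9
  shock: {step_rebound: {initial: -0.2, final: 0.0}}
policy:
  default_k: 0.25
  exclusion_windows:
    - {scope: country, target: null, start: 201904, end: 201910, reason: strike}
model_mode: period
seed: 1
out_dir: out
```

Input CSV schema (UTF-8, header required, empty field = missing value,
period = YYYYMM):

```
district_id,region,area_type,population,period,service,value,reports_expected,reports_actual
```

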