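# glyco

Discrete-time hypoglycemia hazard modelling and glycemic statistics for ICU
cohorts, with a built-in synthetic cohort generator with known ground truth.

The package implements, as a tested reusable pipeline:

- **Glycemic statistics** — hypoglycemia detection (glucose ≤ 70 mg/dL),
  maximal episode construction (6-hour extension rule), time-weighted average
  glucose (LOCF step integration, censored at first onset), coefficient of
  variation, hypoglycemic load, monitoring-frequency metrics.
- **Covariate engineering** — bounded carry-forward imputation (24 h for
  glucose/lactate/MAP, 48 h for daily labs, then cohort-median fallback),
  shock flag (MAP < 60 mmHg or vasopressors), max insulin dose over the
  preceding 12 h (infusions + boluses, hourly bins), dextrose-10%-equivalent
  rates, hourly SOFA scores.
- **Discrete-time hazard dataset** — 6-hour windows per stay, outcome H = 1
  for the window containing the first hypoglycemia onset, censoring
  thereafter, covariates binned to categorical model levels, hospital-level
  insulin-prevalence filter (< 20% excluded).
- **Statistics** — pooled logistic regression with Wald OR CIs, Fox–Monette
  GVIFs, likelihood-ratio χ² for the BMI term, percentile bootstrap (B = 500)
  group means, χ²/Mann–Whitney BMI < 25 vs ≥ 25 comparisons, stratified
  univariate summaries and treatment-exposure tables.
- **Synthetic cohorts** — irregular glucose sampling, configurable per-window
  logistic hazard applied on the binned covariate scale (so parameter-recovery
  tests are exact), mortality driven by BMI group and hypoglycemia.

## CLI

```bash
glyco simulate --seed 7 --n-stays 2000 --out cohort/     # 4 CSVs + truth_table.csv
glyco features   --cohort cohort/ --out glycemia.csv
glyco covariates --cohort cohort/ --times queries.csv --out covariates.csv
glyco windows    --cohort cohort/ --out design.csv [--adjust-diabetes] [--subset low_missingness]
glyco fit        --design design.csv --out fit/          # or_table, gvif, tests CSVs
glyco summarize  --cohort cohort/ --out summaries.csv
glyco run        --seed 7 --out run/                     # full pipeline + manifest
```

`glyco run` accepts `--config cfg.yaml` overriding any `RunConfig` field
(window length, thresholds, bootstrap repetitions, generator scenario, ...);
reruns with the same config and seed are bit-identical.

## Input format

A cohort directory holds four UTF-8 comma-separated files: `stays.csv`
(demographics, height/weight or BMI, admission type, diabetes flag, HbA1c,
ICU length of stay, mortality), `measurements.csv` (`stay_id, variable,
time_h, value` — glucose in mg/dL, times in hours from ICU admission),
`rates.csv` (insulin/dextrose/vasopressor intervals; insulin boluses have
`start_h == end_h`), and `flags.csv` (nutrition/corticosteroid intervals).
Stays without a recorded or derivable BMI are excluded at load.

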