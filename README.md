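# abpmine

Prognostic threshold extraction from ambulatory blood-pressure (ABP)
cohorts: a small, fully tested pipeline that

1. reads reading-level (`subject_id,time_min,sbp,dbp[,hr]`) and
   subject-level (`id,sex,age,bmi,cholesterol,outcome`) CSV tables;
2. applies quality filters (out-of-range readings discarded, subjects with
   fewer than 40 valid readings excluded) and deterministic OLS imputation
   of missing cholesterol on sex and age;
3. computes time-weighted 24-h BP level (WBP) and the Average Real
   Variability index (ARV, the interval-weighted mean absolute successive
   difference) per channel;
4. induces a single conjunctive threshold rule
   (`If <attr> ≥/≤ t … then 1 Else 0`) on the minable attributes:
   univariate logistic screening at `p < 0.01`, a sensitivity-first
   partition search over midpoint cut-points with an epsilon accuracy
   budget, and an optional greedy joint refinement pass against the
   conjunction's confusion matrix;
5. evaluates it with imbalance-preserving stratified k-fold
   cross-validation (pooled held-out confusion matrix) against a
   fold-paired Gaussian naive-Bayes baseline;
6. ships a seeded synthetic-cohort generator (planted threshold rule,
   label noise, AR(1) within-subject BP dynamics calibrated to per-subject
   ARV targets, injectable outliers and missing values) so every stage is
   testable end to end without access to any clinical data.

## CLI

```sh
abpmine simulate   --config cfg.yaml --out sim/          # readings/subjects/truth CSVs
abpmine preprocess --readings R.csv --subjects S.csv --min-readings 40 --out clean/
abpmine indices    --readings clean/readings.csv --out indices.csv
abpmine fit        --features features.csv --alpha 0.01 [--force-attrs cholesterol] \
                   [--joint/--no-joint] --out rule.json
abpmine evaluate   --features features.csv --k 10 --seed 42 --report report.json
abpmine pipeline   --config cfg.yaml [--readings R.csv --subjects S.csv] --out run/
```

`pipeline` runs every stage (simulating a cohort when no input tables are
given) and writes `report.json` (QC counts, per-attribute associations,
the rule string, pooled confusion matrix and metrics) plus the effective
merged config for provenance.  Configuration is YAML with strict key
checking; all defaults equal the standard analysis constants (40-reading
floor, 70–260 / 40–150 mmHg validity ranges, alpha 0.01, 10 folds).

## Layout

```
src/abpmine/
  io.py          reading/subject data model + CSV I/O
  preprocess.py  quality filters, exclusion rule, OLS imputation, QC report
  indices.py     WBP / ARV computation
  rules.py       logistic screening, partition search, rule construction
  evaluation.py  confusion matrix, metrics, stratified k-fold CV, NB baseline
  simulate.py    synthetic cohort generator + artifact injection
  config.py      YAML run configuration
  pipeline.py    stage orchestration and reporting
  cli.py         click entry point
```
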