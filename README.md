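# methylprofiler

Automated QC, linear scoring and percentile-rank profiling of blood DNA
methylation data, plus a cross-validated LASSO recipe for training new
methylation-based trait predictors. The package consumes delimited-text
methylation matrices (beta or M values, either orientation), CpG weight
sets, optional sex/age annotations, optional binary phenotypes and an
optional reference panel, and produces per-sample trait scores, percentile
profiles, case/control summaries and correlation panels — with a plain-text
QC report of every automated step.

## What it does

- **I/O & validation** (`methylprofiler.io`): tolerant reading of
  methylation matrices with automatic orientation (CpG-pattern axis
  becomes columns) and value-scale detection (any value outside [0, 1]
  means M values); sex/age annotations (`ID,Sex,Age`; sex must be `Male`,
  `Female` or `NA`); binary phenotype tables (0 = control, 1 = case);
  CpG truncation lists; lossless score-table round trips.
- **Preprocessing** (`methylprofiler.preprocessing`): M→beta conversion
  (β = 2^M / (2^M + 1)), per-CpG mean imputation across uploaded samples,
  and reference-mean fill for predictor CpGs absent from the upload — a
  per-sample constant that shifts scores toward the reference cohort.
- **Scoring** (`methylprofiler.scoring`): score = intercept + Σ weight ×
  beta per trait, with declared units (years for the age predictor) and
  optional output transforms; weight files are external inputs, never
  bundled.
- **Profiling** (`methylprofiler.profiling`): mid-rank percentiles
  (100·(rank − 0.5)/n, ties averaged; the age trait stays in years),
  individual profiles, case/control median + IQR summaries, inter-predictor
  correlation matrices, and predicted-vs-measured correlations in a
  reference panel — all recomputed dynamically under age/sex/status
  filters, using true age where uploaded and epigenetic age otherwise.
- **Training** (`methylprofiler.training`): phenotype exclusion rules and
  skew transforms, residualization on age + sex + 10 ancestry components,
  optional 450k/EPIC probe-intersection filtering, and LASSO
  (mixing parameter 1) over a 100-value lambda path with 10-fold CV at the
  minimum mean CV error, returning beta-scale weight files the scoring
  module loads directly.
- **Synthetic data** (`methylprofiler.synthetic`): fully seeded cohort
  simulations (bimodal Beta-mixture methylation, linear phenotypes with
  known causal CpGs, annotations, case/control statuses, reference panels)
  and a CSV fixture bundle that exercises every QC path.

## CLI

```sh
# generate a synthetic fixture bundle with known ground truth
methylprofiler simulate --seed 7 -o fixtures/

# shrink an upload to the CpGs the score sets need
methylprofiler truncate --matrix fixtures/methylation.csv \
    --cpgs fixtures/truncate_cpgs.csv -o small.csv

# full QC + scoring pipeline (orient -> detect -> convert -> impute -> fill -> score)
methylprofiler score --matrix small.csv --weights fixtures/weights.csv \
    --manifest fixtures/manifest.yml --sexage fixtures/sexageinfo.csv \
    --reference-panel fixtures/panel.csv -o scores.csv --log qc.txt

# percentile ranks, case/control summary, correlations, with filtering
methylprofiler profile --scores scores.csv --phenotypes fixtures/case_control.csv \
    --phenotype BMI --age-range 40 60 --sex Female \
    -o ranks.csv --summary-out summary.csv

# train a new predictor (LASSO, 10-fold CV, lambda at min CV error)
methylprofiler train --matrix train.csv --pheno pheno.csv \
    --covars covars.csv --seed 1 -o weights.csv
```

The QC log reports each automated action with counts (transposition,
M→beta conversion, imputed cells, reference-filled CpGs) and is written
even when a run fails.

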