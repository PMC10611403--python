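# mmjive

Measuring shared ("joint") information between two blocks of wearable-device
features collected repeatedly across days — e.g. daily gait summaries from a
lumbar accelerometer and daily physical-activity (PA) summaries from a wrist
accelerometer.  The package implements a layered analytic framework:

- **Panel model** (`mmjive.panel`): long-format `(subject, day)` tables with
  two disjoint feature blocks, validation, valid-day filtering (≥ 10 h wear
  time), column z-scoring with two scopes (daily rows, or subject means so
  that one-level inputs are exactly standardized), and day-averaging.
- **Synthetic generator** (`mmjive.synthetic`): two-block multilevel panels
  with planted joint/individual low-rank structure and a known variance
  partition at the between- and within-subject levels, so every downstream
  estimator is testable for parameter recovery without external data.
- **Feature-on-domain models** (`mmjive.feature_models`): pairwise Pearson
  correlation matrices with exact t-test p-values, Lasso regression of each
  feature on the opposite block (100-point log lambda grid, five-fold CV,
  one-standard-error rule), and principal-component regression with
  ≥ 90 %-variance (default) or scree-elbow component selection.
- **Domain-on-domain models** (`mmjive.domain_models`): two-block PLS in
  regression mode (weight pairs maximizing the cross-block covariance
  `u'X'Yv`, both blocks deflated on x-scores) and an iterative
  joint + individual + residual decomposition of the stacked blocks with
  row-space orthogonality, variance-explained accounting, and
  permutation-based rank selection.
- **Multilevel extensions** (`mmjive.multilevel`): exact
  grand-mean/between/within decomposition, multilevel PCA (cross-day moment
  estimator of the between covariance, PSD-projected), per-level PLS and
  two-step multilevel JIVE, score–feature correlation reports, and
  cross-model component comparison on a common subject grain.
- **Pipeline** (`mmjive.report`, `mmjive.cli`): a single `run_all`
  orchestrating everything with deterministic CSV outputs and a JSON
  manifest; reruns with the same seed are byte-identical.

## CLI

Generate a synthetic study-shaped panel and run the full framework:

```bash
mmjive simulate --out panel.csv --truth-out truth/ --seed 7
mmjive all --in panel.csv --domains panel.domains.csv --out report/ --seed 7
```

Single stages: `correlate`, `lasso`, `pcr`, `pls`, `jive`, `ml-pls`,
`ml-jive`, `compare`.  Inputs are a panel CSV with `subject`, `day`,
optional `wear_hours`, and feature columns, plus a two-column
`feature,domain` CSV with domain ∈ {PA, gait}.  Settings can be given as a
TOML file via `--config` (keys match `mmjive.report.RunConfig`); every
default is echoed into `manifest.json`.

The report bundle contains `correlations.csv`, `correlation_pvalues.csv`,
`lasso_coefficients.csv`, `pca_loadings.csv`, `pcr_coefficients.csv`,
`pls_weights.csv`, `pls_correlation_circle.csv`, `jive_variance_table.csv`,
`jive_structures/*.csv`, `mlpls_loadings_{between,within}.csv`,
`mljive_level_table.csv`, `mljive_score_correlations_{between,within}.csv`,
`component_comparison.csv`, and `manifest.json`.  Cells meaning "not
selected" / "not significant" are written as empty fields, never NaN.

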