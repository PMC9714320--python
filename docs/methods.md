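# Methods

This note describes the statistical procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
data used in the tests does and does not show about real data.

## The problem and the pipeline

Radiogenomics asks whether quantitative imaging features of a tumor region
of interest (size, shape, texture, intensity, kinetic and wavelet measures)
carry information about the tumor's molecular profile, e.g. normalized
gene-expression values (FPKM). The package takes two CSV tables over a
shared sample set — a samples × imaging-features matrix and a samples ×
omics-features matrix — and runs a configurable association experiment:

1. **Matching and screening.** Samples are matched by exact ID string; the
   omics table may be screened to features with value ≥ *v* in ≥ *k*
   samples (the conventional expression screen, e.g. FPKM ≥ 5 in ≥ 30
   patients), which removes unexpressed genes before any testing.
2. **Correlation filtering (Scenario A).** Every (imaging, omics) pair is
   tested with Pearson or Spearman correlation on the raw matched data
   (the correlation stage deliberately precedes normalization).  Two-sided
   p-values come from the t-distribution on *r* with *n* − 2 degrees of
   freedom; Spearman is Pearson on average ranks.  All pair p-values are
   pooled and adjusted with one of holm / hochberg / hommel / bonferroni /
   BH / BY (`fdr` aliases BH, following R's `p.adjust` vocabulary).  A pair
   survives when |r| > *t* (default 0.5) **and** adjusted p < 0.05, both
   strict; a feature survives when it belongs to at least one surviving
   pair.  Setting *t* = −1.0 disables the filter and passes every feature
   downstream.
3. **Split and normalization.** One seeded uniform train/test split (no
   stratification) is shared by everything downstream.  Features and labels
   are both scaled with the configured scaler (standard scaler, min–max, or
   max-abs).  By default the scaler is fitted *independently* on the train
   and the test partition — the same technique fitted twice — so no test
   statistics enter training; `scaler_fit: train_only` provides the
   conventional fit-on-train/apply-to-test alternative.  Standard
   deviations use the population convention (ddof = 0) throughout.
4. **Modeling.** Six regression families: ordinary linear, LASSO, elastic
   net, multi-task LASSO, multi-task elastic net (group-sparse across
   labels), and decision trees.  Linear families fit all labels through one
   scikit-learn estimator; the decision-tree family fits one regressor per
   label so per-label importances are well defined.  K-fold CV (contiguous
   unshuffled folds by default, cv = 2 default) reports per-fold negative
   MSE; optional exhaustive grid search maximizes mean CV negative MSE with
   first-in-grid tie-breaking, then refits on the full training set.
5. **Evaluation.** Per label on the test split:
   MSE, RMSE, population STDEV of the observed values, the ratio
   **v = RMSE/STDEV = √(SSL/SST)**, and R² computed two ways — directly as
   1 − SSL/SST and through the identity **R² = 1 − v²**.  The two agree to
   1e-9 by construction (this is exactly why the population convention is
   used); v = 1 means no better than predicting the label mean, v > 1
   (R² < 0) means worse.
   To judge the regression as a high/low classifier, observed label values
   are min–max rescaled to [0, 1] and binarized at each decision threshold
   dt ∈ {0.1, …, 1.0} (value < dt → 0, value ≥ dt → 1 — a value exactly at
   the threshold goes high); predictions stay continuous and act as ranking
   scores for a Mann–Whitney AUC with 0.5 credit for ties.  Thresholds that
   leave a single class have no defined AUC and are reported as missing.
   The per-label *headline AUC* is the maximum defined AUC over the grid,
   reported together with the dt range achieving it.
6. **Significance.** Labels with headline AUC > 0.9 **and** test R² > 0.25
   (strict) are permutation-tested: the label's training values are
   shuffled across samples, the model refit, and the test split re-scored;
   p = #{permuted statistic ≥ observed}/n_perm (default n_perm = 100, so
   p resolves to 0.01 and p = 0 is attainable).  An opt-in smoothed variant
   gives (count + 1)/(n_perm + 1).
7. **Scenario B (model-selected features).** In the same run the
   correlation stage is bypassed entirely: a pilot model is trained on all
   features, features are kept when their importance score reaches the mean
   score (tree importance averaged over labels, or the per-feature L2 norm
   of the coefficient column for linear families — L2 because it is the
   natural group magnitude for multi-task coefficient matrices), and the
   model is retrained on the kept features.  All Scenario B artifacts live
   under a `FeaturesSelFromModel`-prefixed subdirectory.  Both scenarios
   share the single split so their metrics are comparable.
8. **Reporting.** A self-contained five-section HTML report (input summary;
   clustered correlation heat maps; surviving features and train/test
   parameters; model interpretation with the v bar plot, true-vs-predicted
   scatter restricted to labels with v ≤ 1, and the AUC-vs-dt plot;
   permutation summaries), plus machine-readable CSVs for every table, a
   run log, a resolved config snapshot, and a reloadable model file.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `correlation_method` | spearman | pair test; pearson optional |
| `correlation_threshold` | 0.5 | strict lower bound on \|r\|; −1.0 disables |
| `p_correction` | BH | multiplicity adjustment over all pairs |
| `p_threshold` | 0.05 | strict upper bound on adjusted p |
| `train_size` / `test_size` | 0.9 / 0.1 | split fractions (test = round(f·n)) |
| `normalization` | stand_scaler | also min_max, max_abs; applied to X and Y |
| `scaler_fit` | independent | train and test scaled separately; `train_only` optional |
| `model_type` | decision_tree | one of the six families |
| `cv` | 2 | K-fold splits for the reported CV scores |
| `n_permutations` | 100 | permutation-test resolution (p multiples of 0.01) |

Unspecified model hyperparameters fall back to a frozen default table
(`modeling.DEFAULT_HYPERPARAMETERS`) mirroring scikit-learn's documented
defaults — regularized families use coordinate descent with tol 1e-4 and
max 1000 iterations, both configurable.  Note that the default
regularization strength `alpha = 1.0` is a heavy penalty on standardized
data (it soft-thresholds standardized coefficients by ~0.5); experiments on
standardized inputs should set `alpha` to a value appropriate for their
signal scale or use grid search — the worked examples use 0.1.

## Numerical choices and degenerate inputs

- Constant features map to 0 under any scaler (division-by-zero guard, with
  a warning); zero-variance features get r = 0, p = 1 in the correlation
  stage rather than NaNs.
- A constant observed label leaves v and R² undefined; the label is
  reported with its MSE and flagged, and can never be gated.
- The dt sweep needs observed values in [0, 1]; since the model-space
  scaler may be the standard scaler, the sweep min–max rescales y_obs
  independently and pushes y_pred through the same affine map, which
  preserves ranking and therefore every AUC.
- Heat-map ordering uses average-linkage agglomeration on the 1 − |r|
  profile-correlation distance, rendered as three views (raw pairwise,
  row-clustered, biclustered) of the same coefficient matrix.
- Grid-search ties keep the first candidate in grid order; normalization
  is done once on the full training set before CV, not per fold.
- Missing or non-numeric cells are rejected at load with coordinates —
  a metrics pipeline should fail loudly rather than impute.
- The model file is a JSON metadata header (spec, features, labels, scaler
  statistics, CV scores) followed by the pickled estimator payload; a
  round trip reproduces bitwise-identical predictions.
- Permutation refits for label-independent families (linear, lasso,
  elastic net, decision tree) refit only the permuted label's column —
  mathematically identical to refitting the full multi-output model and
  about n_labels times faster; multi-task families refit the full coupled
  model.
- The AUC permutation p-value is conservative by construction: the
  headline statistic is a max over the dt grid, and at extreme thresholds
  a single positive gives a random ranking AUC = 1 with probability about
  1/n_test.  The R² permutation p uses a continuous statistic and is the
  sharper significance measure; both are reported, and the calibration and
  recovery checks in the test suite use p(R²).

## The synthetic generator

`SyntheticDesign` emulates the shape of real radiogenomic inputs with a
known ground truth: `n_informative_features` imaging features (independent
standard normals) linearly drive `n_planted_labels` omics labels through
2 equally weighted drivers each, plus Gaussian noise with sd `noise_sd`
relative to unit signal sd; planted labels are min–max mapped to [0, 1] so
the dt grid is meaningful, and decoy labels are independent uniforms on
[0, 1].  Defaults: 120 samples, 40 imaging features (4 informative), 30
labels (6 planted), noise_sd = 1/3 — i.e. a best-achievable R² of 0.9 and
a per-(driver, label) population correlation √(0.9/2) ≈ 0.67, comfortably
above the 0.5 filter threshold.  `null_dataset` draws fully independent
tables for calibration checks.

What it does **not** emulate: correlated radiomic feature blocks, count- or
log-normal-distributed expression, batch effects, missingness.  Passing the
planted-recovery checks therefore demonstrates that the machinery finds a
linear, well-separated signal and stays quiet on independent noise — not
that it will untangle correlated real cohorts.

## Problem sizes used in the checks

The test suite and the acceptance script run at deliberately small sizes
chosen to exercise every code path with stable statistics: 1,000 random
pairs for the R² identity, 1,000 instances for the AUC oracle, 200 random
p-vectors for the adjustment oracles, 50 × 20 vs 50 × 30 tables for the
correlation recomputation, 300–500 null replicates at n_perm = 100 for
calibration (1% Kolmogorov–Smirnov criterion), and 10–20 seeded replicates
of the default design for end-to-end recovery with the decision-tree and
elastic-net (alpha 0.1) pipelines.

## Known limitations

- Correlation p-values use the t-approximation, adequate for n ≳ 10; no
  exact permutation p for tiny n.
- The independent train/test scaler fit (the default policy) means
  Validate/Predict results depend on the new dataset's own scale statistics;
  use `train_only` when the new data's scale cannot be trusted.
- Per-label permutation tests are not corrected across labels; p-values
  are per-label, as reported.
- No survival, classification, boosting or neural model families; no
  partial correlation or network inference.
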