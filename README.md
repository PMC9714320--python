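# imagene

**Radiogenomic association engine**: find and validate associations between
tumor imaging (radiomic) features and omics features (e.g. normalized
gene expression) of the same samples.

Quantitative features extracted from tumor regions of interest on CT/MRI/PET
images — size, shape, texture, intensity, wavelet measures — can carry
information about the tumor's molecular profile.  This package takes two CSV
tables over a shared sample set (samples × imaging features, samples × omics
features) and runs a fully configurable, reproducible experiment:

1. **correlation filtering** — Pearson/Spearman tests for every
   (imaging, omics) pair with multiplicity control (BH/BY/Holm/Hochberg/
   Hommel/Bonferroni); pairs survive when |r| > threshold and adjusted
   p < 0.05;
2. **regression modeling** — linear, LASSO, elastic net, their multi-task
   (group-sparse) variants, or decision trees, predicting the label table
   from the data table, with K-fold CV and optional grid search;
3. **per-label evaluation** — MSE, RMSE, and the ratio
   **v = RMSE/STDEV = √(SSL/SST)** with its companion identity
   **R² = 1 − v²** (population-variance convention, so both R² routes agree
   to 1e-9); plus a decision-threshold sweep that binarizes observed labels
   at dt ∈ {0.1, …, 1.0} and scores the continuous predictions with a
   rank-based AUC at every threshold;
4. **permutation significance** — labels with headline AUC > 0.9 and test
   R² > 0.25 are re-tested by shuffling their training values and refitting;
   p = #{permuted ≥ observed}/n_perm;
5. **model-based feature selection** — in the same run a second scenario
   bypasses correlation entirely, keeps features whose model importance
   reaches the mean score, and retrains; its outputs land in a
   `FeaturesSelFromModel`-prefixed subdirectory;
6. **reporting** — a self-contained five-section HTML report with clustered
   correlation heat maps, the v bar plot, true-vs-predicted scatter
   (labels with v ≤ 1), AUC-vs-dt curves, and permutation summaries,
   alongside machine-readable CSVs, a run log, a config snapshot and a
   reloadable model file.

A seeded synthetic-data generator with planted linear associations makes
every stage testable without any external downloads.  See
[docs/methods.md](docs/methods.md) for the full statistical account.

## Worked example

```python
from imagene import SyntheticDesign, write_dataset, ExperimentConfig, run_train

# 120 samples, 40 imaging features (4 informative), 30 labels (6 planted)
paths = write_dataset(SyntheticDesign(seed=1), "example_data")

config = ExperimentConfig(
    seed=1, train_size=0.8, test_size=0.2,
    model_type="elastic_net", model_params={"alpha": 0.1},
    output_dir="example_run",
)
art = run_train(config, paths[0], paths[1])

corr = art.scenario_a.correlation
print(corr.surviving_imaging)   # data features passing |rho|>0.5, BH p<0.05
print(corr.surviving_omics)     # labels passing the same filter
```

```
['IMG001', 'IMG002', 'IMG003', 'IMG004']
['GENE001', 'GENE002', 'GENE003', 'GENE004', 'GENE005', 'GENE006']
```

The correlation stage recovered exactly the 4 informative imaging features
and the 6 planted labels; the 36 noise features and 24 decoy labels were
filtered out.  The per-label test metrics (`example_run/metrics.csv`):

```
  label  RMSE  STDEV     v  R2_direct  AUC_max best_dt_range
GENE001 0.238      1 0.238      0.943        1      [0.5, 1]
GENE002 0.331      1 0.331      0.890        1      [0.1, 1]
GENE003 0.324      1 0.324      0.895        1      [0.3, 1]
GENE004 0.356      1 0.356      0.873        1    [0.1, 0.9]
GENE005 0.340      1 0.340      0.884        1      [0.1, 1]
GENE006 0.332      1 0.332      0.890        1      [0.1, 1]
```

`v` is the prediction error as a fraction of the label's spread — 0.24
means residuals are a quarter of the observed standard deviation — and
`R2_direct` equals `1 − v²` by the identity.  `AUC_max` = 1 with a wide
best-dt range says the model separates high from low label values
perfectly at almost any cutoff.  All six labels clear the AUC > 0.9,
R² > 0.25 gate and survive permutation testing
(`example_run/permutation_pvalues.csv`):

```
  label  AUC_test  R2_test  n_permutations  p_AUC  p_R2
GENE001         1    0.943             100   0.17     0
GENE002         1    0.890             100   0.13     0
...
```

`p_R2 = 0`: no permutation reached the observed R² in 100 tries.  (`p_AUC`
is conservative by construction — the headline AUC is a max over the dt
grid, which permuted models can also occasionally hit at extreme
thresholds; see docs/methods.md.)  The second scenario's outputs, trained
on model-selected features with correlation bypassed, are under
`example_run/FeaturesSelFromModel_results/`, and `example_run/report.html`
collects everything.

The same experiment from a shell:

```bash
imagene synth --outdir example_data --seed 1
imagene run --imaging example_data/imaging.csv --omics example_data/omics.csv \
            --config cfg.yaml --outdir example_run --seed 1
```

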