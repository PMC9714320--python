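"""Two-scenario experiment orchestration, run modes and job artifacts.

A Train-mode run executes two automated scenarios on one shared train/test
split:

* **Scenario A (correlation-filtered)** — correlate data and label features
  on the raw matched tables, keep pairs with |r| above the coefficient
  threshold and adjusted p below 0.05, split, normalize, train, evaluate on
  the test split, gate, permutation-test.
* **Scenario B (model-selected)** — bypass correlation entirely: split,
  normalize, train on all features, keep features whose importance score
  reaches the mean (tree importances, or the per-feature L2 norm of the
  coefficient column for linear families), retrain on the kept features and
  evaluate the same way.  All Scenario B artifacts live in a subdirectory
  prefixed ``FeaturesSelFromModel``.

Validate mode re-evaluates a stored model on any number of new dataset
pairs; Predict mode emits continuous predictions for a new data table.
Every run writes a resolved config snapshot and a run log first, then the
artifact set (correlation tables, heat maps, metrics, AUC-vs-dt curves,
feature weights, "validation permuts" files, model file, HTML report).
"""

from __future__ import annotations

import json
import re
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import report as _report
from .correlation import (
    ADJUSTMENT_METHODS,
    CORRELATION_METHODS,
    CorrelationResult,
    filter_by_correlation,
)
from .data_io import (
    ConfigError,
    FeatureTable,
    SCALER_METHODS,
    SplitSpec,
    ValidationError,
    apply_scaler,
    fit_scaler,
    load_feature_table,
    match_samples,
    screen_omics,
    split_train_test,
)
from .evaluation import (
    DtGrid,
    LabelEvaluation,
    auc_curve_frame,
    evaluate_labels,
    export_feature_weights,
    metrics_frame,
)
from .modeling import (
    MODEL_TYPES,
    ModelSpec,
    TrainedModel,
    load_model,
    predict_matrix,
    save_model,
    train,
)
from .significance import (
    PermutationResult,
    gate_labels,
    permutation_test,
    summary_frame,
)

#: Prefix of the Scenario B output subdirectory.
SELECT_FROM_MODEL_PREFIX = "FeaturesSelFromModel"

_CSV_FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Full experiment parameter set (defaults mirror the platform's)."""

    correlation_method: str = "spearman"       # or "pearson"
    correlation_threshold: float = 0.5         # -1.0 disables filtering
    p_correction: str = "BH"
    p_threshold: float = 0.05
    data_role: str = "imaging"                 # or "gene"
    label_role: str = "gene"                   # or "imaging"
    train_size: float = 0.9
    test_size: float = 0.1
    normalization: str = "stand_scaler"        # min_max | max_abs
    scaler_fit: str = "independent"            # or "train_only"
    mode: str = "train"                        # validate | predict
    model_type: str = "decision_tree"
    grid_search: bool = False
    cv: int = 2
    model_params: dict[str, Any] = field(default_factory=dict)
    grid_params: dict[str, list[Any]] = field(default_factory=dict)
    screen_min_value: float | None = None      # e.g. 5 (FPKM screen)
    screen_min_samples: int | None = None      # e.g. 30
    selection_threshold: float | None = None   # None = mean importance
    n_permutations: int = 100
    smoothed_p: bool = False
    seed: int = 0
    output_dir: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.correlation_method not in CORRELATION_METHODS:
            raise ConfigError(
                f"unknown correlation method {self.correlation_method!r}"
            )
        if self.p_correction not in ADJUSTMENT_METHODS:
            raise ConfigError(f"unknown p correction {self.p_correction!r}")
        roles = {"imaging", "gene"}
        if self.data_role not in roles or self.label_role not in roles:
            raise ConfigError("data/label roles must be 'imaging' or 'gene'")
        if self.data_role == self.label_role:
            raise ConfigError("data_role and label_role must differ")
        if self.normalization not in SCALER_METHODS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.scaler_fit not in ("independent", "train_only"):
            raise ConfigError(f"unknown scaler_fit {self.scaler_fit!r}")
        if self.mode not in ("train", "validate", "predict"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.model_type not in MODEL_TYPES:
            raise ConfigError(f"unknown model type {self.model_type!r}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        # fraction checks delegated to SplitSpec
        SplitSpec(self.train_size, self.test_size, self.seed)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            model_type=self.model_type,
            hyperparameters=dict(self.model_params),
            grid={k: list(v) for k, v in self.grid_params.items()} or None,
            cv_folds=self.cv,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Everything one scenario produced (empty=True when it had no features)."""

    name: str
    empty: bool
    correlation: CorrelationResult | None
    selected_features: list[str] | None
    model: TrainedModel | None
    evaluations: list[LabelEvaluation]
    gated: list[str]
    permutations: list[PermutationResult]
    Y_obs_test: np.ndarray | None
    Y_pred_test: np.ndarray | None


@dataclass
class JobArtifacts:
    job_dir: Path
    report_path: Path | None
    scenario_a: ScenarioResult | None
    scenario_b: ScenarioResult | None
    model_paths: dict[str, Path]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", label)


def _assign_roles(
    config: ExperimentConfig, imaging: FeatureTable, omics: FeatureTable
) -> tuple[FeatureTable, FeatureTable]:
    """Map the two tables onto (data X, labels Y) per the configured roles."""
    if config.data_role == "imaging":
        return imaging, omics
    return omics, imaging


def _normalize_pair(
    config: ExperimentConfig,
    x_train: FeatureTable,
    y_train: FeatureTable,
    x_test: FeatureTable,
    y_test: FeatureTable,
):
    """Scale train and test; returns scaled tables + train-fitted params."""
    px = fit_scaler(x_train, config.normalization)
    py = fit_scaler(y_train, config.normalization)
    if config.scaler_fit == "independent":
        px_test = fit_scaler(x_test, config.normalization)
        py_test = fit_scaler(y_test, config.normalization)
    else:
        px_test, py_test = px, py
    return (
        apply_scaler(x_train, px),
        apply_scaler(y_train, py),
        apply_scaler(x_test, px_test),
        apply_scaler(y_test, py_test),
        px,
        py,
    )


def select_features_from_model(
    m: TrainedModel, threshold: float | None = None
) -> list[str]:
    """Features whose importance score reaches the threshold (default: mean).

    Score = tree feature importance averaged over per-label trees, or the
    L2 norm across labels of each coefficient column for linear families.
    Falls back to the single top-scoring feature (with a warning) if the
    threshold would select nothing.
    """
    if m.is_tree:
        per_label = np.vstack(
            [m.label_weights(lbl) for lbl in m.label_names]
        )
        scores = per_label.mean(axis=0)
    else:
        coef = m.coefficient_matrix()
        scores = np.sqrt((coef**2).sum(axis=0))
    thr = float(np.mean(scores)) if threshold is None else threshold
    # tolerance so identically-important features all clear the mean
    tol = 1e-12 * max(1.0, abs(thr))
    keep = [f for f, s in zip(m.feature_names, scores) if s >= thr - tol]
    if not keep:
        warnings.warn(
            "importance threshold selected no features; keeping the top-1",
            stacklevel=2,
        )
        keep = [m.feature_names[int(np.argmax(scores))]]
    return keep


def _run_scenario(
    config: ExperimentConfig,
    name: str,
    x_train: FeatureTable,
    y_train: FeatureTable,
    x_test: FeatureTable,
    y_test: FeatureTable,
    correlation: CorrelationResult | None,
    select_from_model: bool,
    log: list[str],
) -> ScenarioResult:
    """Normalize, (optionally model-select features,) train, evaluate, gate,
    permute.  Feature/label subsetting has already happened for Scenario A."""
    xs_tr, ys_tr, xs_te, ys_te, px, py = _normalize_pair(
        config, x_train, y_train, x_test, y_test
    )
    spec = config.model_spec()
    selected: list[str] | None = None

    if select_from_model:
        pilot = train(
            spec,
            xs_tr.values,
            ys_tr.values,
            xs_tr.feature_names,
            ys_tr.feature_names,
            px,
            py,
            use_grid=config.grid_search,
        )
        selected = select_features_from_model(pilot, config.selection_threshold)
        log.append(
            f"{name}: model-based selection kept {len(selected)} of "
            f"{len(xs_tr.feature_names)} features"
        )
        x_train = x_train.select_features(selected)
        x_test = x_test.select_features(selected)
        xs_tr, ys_tr, xs_te, ys_te, px, py = _normalize_pair(
            config, x_train, y_train, x_test, y_test
        )

    model = train(
        spec,
        xs_tr.values,
        ys_tr.values,
        xs_tr.feature_names,
        ys_tr.feature_names,
        px,
        py,
        use_grid=config.grid_search,
    )
    Y_pred = predict_matrix(model, xs_te.values)
    evals = evaluate_labels(model.label_names, ys_te.values, Y_pred)
    gated = gate_labels(evals)
    log.append(
        f"{name}: trained {config.model_type} on "
        f"{len(model.feature_names)} features / {len(model.label_names)} "
        f"labels; {len(gated)} label(s) cleared the gate"
    )
    perms = [
        permutation_test(
            spec,
            xs_tr.values,
            ys_tr.values,
            xs_te.values,
            ys_te.values[:, model.label_names.index(lbl)],
            lbl,
            model.label_names,
            n_perm=config.n_permutations,
            seed=config.seed + 1 + model.label_names.index(lbl),
            params=model.chosen_params,
            smoothed=config.smoothed_p,
        )
        for lbl in gated
    ]
    return ScenarioResult(
        name=name,
        empty=False,
        correlation=correlation,
        selected_features=selected,
        model=model,
        evaluations=evals,
        gated=gated,
        permutations=perms,
        Y_obs_test=ys_te.values,
        Y_pred_test=Y_pred,
    )


def _write_scenario(
    config: ExperimentConfig,
    sc: ScenarioResult,
    out_dir: Path,
    n_train: int,
    n_test: int,
) -> tuple[dict, Path | None]:
    """Write one scenario's artifact files; returns (report section, model path)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    section: dict[str, Any] = {"title": sc.name, "empty": sc.empty}

    corr_images: list[Path] = []
    if sc.correlation is not None:
        sc.correlation.to_frame().to_csv(
            out_dir / "correlations.csv", index=False,
            float_format=_CSV_FLOAT_FORMAT,
        )
        if config.make_plots:
            corr_images = _report.correlation_heatmaps(sc.correlation, out_dir)
    section["correlation_images"] = corr_images

    if sc.empty or sc.model is None:
        return section, None

    if sc.selected_features is not None:
        (out_dir / "selected_features.txt").write_text(
            "\n".join(sc.selected_features) + "\n"
        )

    model_path = out_dir / "model.imagene"
    save_model(sc.model, model_path)

    mdf = metrics_frame(sc.evaluations)
    mdf.to_csv(out_dir / "metrics.csv", index=False, float_format=_CSV_FLOAT_FORMAT)

    auc_dir = out_dir / "auc_dt"
    auc_dir.mkdir(exist_ok=True)
    for e in sc.evaluations:
        auc_curve_frame(e).to_csv(
            auc_dir / f"{_safe_name(e.label_name)}.csv", index=False,
            float_format=_CSV_FLOAT_FORMAT,
        )

    export_feature_weights(sc.model).to_csv(
        out_dir / "feature_weights.csv", index=False,
        float_format=_CSV_FLOAT_FORMAT,
    )

    perm_dir = out_dir / "validation_permuts"
    perm_dir.mkdir(exist_ok=True)
    for pr in sc.permutations:
        pr.to_frame().to_csv(
            perm_dir / f"validation_permuts_{_safe_name(pr.label_name)}.txt",
            sep="\t", index=False, float_format=_CSV_FLOAT_FORMAT,
        )
    summary_frame(sc.permutations).to_csv(
        out_dir / "permutation_pvalues.csv", index=False,
        float_format=_CSV_FLOAT_FORMAT,
    )

    images: dict[str, Path | None] = {}
    if config.make_plots:
        images["RMSE:STDEV bar plot"] = _report.v_bar_plot(
            sc.evaluations, out_dir / "v_ratio_bar.png"
        )
        images["true vs predicted"] = _report.scatter_plot(
            sc.evaluations,
            sc.Y_obs_test,
            sc.Y_pred_test,
            sc.model.label_names,
            out_dir / "true_vs_predicted.png",
        )
        images["AUC vs dt"] = _report.auc_dt_plot(
            sc.evaluations, out_dir / "auc_vs_dt.png"
        )

    surviving = {
        "features": list(sc.model.feature_names),
        "labels": list(sc.model.label_names),
    }
    params = pd.DataFrame(
        [
            {"parameter": "model type", "value": config.model_type},
            {"parameter": "normalization", "value": config.normalization},
            {"parameter": "train size", "value": config.train_size},
            {"parameter": "test size", "value": config.test_size},
            {"parameter": "n train / n test", "value": f"{n_train} / {n_test}"},
            {"parameter": "cv", "value": config.cv},
            {"parameter": "grid search", "value": config.grid_search},
            {"parameter": "chosen params", "value": json.dumps(sc.model.chosen_params)},
        ]
    )
    section.update(
        surviving=surviving,
        parameters=params,
        metrics=mdf,
        cv_scores=list(sc.model.cv_scores),
        images=images,
        permutation_summary=summary_frame(sc.permutations),
    )
    return section, model_path


def _prepare_job_dir(config: ExperimentConfig) -> Path:
    if config.output_dir is not None:
        job_dir = Path(config.output_dir)
    else:
        run_id = time.strftime("run_%Y%m%d-%H%M%S")
        job_dir = Path("imagene_runs") / run_id
    job_dir.mkdir(parents=True, exist_ok=True)
    return job_dir


def _snapshot(config: ExperimentConfig, job_dir: Path) -> None:
    (job_dir / "config_snapshot.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# Run modes
# ---------------------------------------------------------------------------

def run_train(
    config: ExperimentConfig,
    imaging_csv: str | Path,
    omics_csv: str | Path,
) -> JobArtifacts:
    """Full two-scenario Train-mode run; returns the job artifact handle."""
    job_dir = _prepare_job_dir(config)
    _snapshot(config, job_dir)
    log: list[str] = [f"mode=train seed={config.seed}"]

    imaging = load_feature_table(imaging_csv, "imaging")
    omics = load_feature_table(omics_csv, "omics")
    imaging, omics = match_samples(imaging, omics)
    log.append(f"matched {imaging.n_samples} common samples")
    if config.screen_min_value is not None and config.screen_min_samples is not None:
        before = omics.n_features
        omics = screen_omics(
            omics, config.screen_min_value, config.screen_min_samples
        )
        log.append(f"omics screen kept {omics.n_features} of {before} features")

    x_full, y_full = _assign_roles(config, imaging, omics)
    split = SplitSpec(config.train_size, config.test_size, config.seed)
    (x_train, y_train), (x_test, y_test) = split_train_test(x_full, y_full, split)
    log.append(f"split: {x_train.n_samples} train / {x_test.n_samples} test")

    # ---- Scenario A: correlation-filtered -------------------------------
    corr = filter_by_correlation(
        x_full,
        y_full,
        method=config.correlation_method,
        coefficient_threshold=config.correlation_threshold,
        correction_method=config.p_correction,
        p_threshold=config.p_threshold,
    )
    log.append(
        f"correlation ({config.correlation_method}, threshold "
        f"{config.correlation_threshold}): {len(corr.surviving_imaging)} data "
        f"and {len(corr.surviving_omics)} label features survive"
    )
    if not corr.surviving_imaging or not corr.surviving_omics:
        warnings.warn(
            "no features survived correlation filtering; Scenario A is empty",
            stacklevel=2,
        )
        log.append("Scenario A empty (no surviving features)")
        scenario_a = ScenarioResult(
            name="Scenario A (correlation-filtered)",
            empty=True,
            correlation=corr,
            selected_features=None,
            model=None,
            evaluations=[],
            gated=[],
            permutations=[],
            Y_obs_test=None,
            Y_pred_test=None,
        )
    else:
        scenario_a = _run_scenario(
            config,
            "Scenario A (correlation-filtered)",
            x_train.select_features(corr.surviving_imaging),
            y_train.select_features(corr.surviving_omics),
            x_test.select_features(corr.surviving_imaging),
            y_test.select_features(corr.surviving_omics),
            corr,
            select_from_model=False,
            log=log,
        )

    # ---- Scenario B: model-selected features (correlation bypassed) -----
    scenario_b = _run_scenario(
        config,
        "Scenario B (model-selected features)",
        x_train,
        y_train,
        x_test,
        y_test,
        None,
        select_from_model=True,
        log=log,
    )

    # ---- Artifacts -------------------------------------------------------
    n_tr, n_te = x_train.n_samples, x_test.n_samples
    section_a, model_a = _write_scenario(config, scenario_a, job_dir, n_tr, n_te)
    sub = job_dir / f"{SELECT_FROM_MODEL_PREFIX}_results"
    section_b, model_b = _write_scenario(config, scenario_b, sub, n_tr, n_te)

    model_paths = {}
    if model_a is not None:
        model_paths["scenario_a"] = model_a
    if model_b is not None:
        model_paths["scenario_b"] = model_b

    input_summary = {
        "imaging features file": str(imaging_csv),
        "omics features file": str(omics_csv),
        "common samples": imaging.n_samples,
        "data role": config.data_role,
        "label role": config.label_role,
        "normalization method": config.normalization,
        "scaler fitting": config.scaler_fit,
        "correlation method": config.correlation_method,
        "correlation threshold": config.correlation_threshold,
        "p correction": config.p_correction,
        "seed": config.seed,
    }
    report_path = _report.render_report(
        job_dir, input_summary, [section_a, section_b]
    )
    log.append(f"report written to {report_path.name}")
    (job_dir / "run.log").write_text("\n".join(log) + "\n")

    return JobArtifacts(
        job_dir=job_dir,
        report_path=report_path,
        scenario_a=scenario_a,
        scenario_b=scenario_b,
        model_paths=model_paths,
    )


def run_validate(
    config: ExperimentConfig,
    model_file: str | Path,
    test_sets: list[tuple[str | Path, str | Path]],
) -> tuple[Path, list[list[LabelEvaluation]]]:
    """Evaluate a stored model, unchanged, on each (imaging, omics) CSV pair.

    Writes one metrics/AUC-curve set per dataset into the job directory and
    returns the per-dataset evaluations.
    """
    job_dir = _prepare_job_dir(config)
    _snapshot(config, job_dir)
    model = load_model(model_file)
    log: list[str] = [f"mode=validate model={model_file}"]
    all_evals: list[list[LabelEvaluation]] = []
    for k, (imaging_csv, omics_csv) in enumerate(test_sets, start=1):
        imaging = load_feature_table(imaging_csv, "imaging")
        omics = load_feature_table(omics_csv, "omics")
        imaging, omics = match_samples(imaging, omics)
        x_tbl, y_tbl = _assign_roles(config, imaging, omics)
        missing = [f for f in model.feature_names if f not in x_tbl.feature_names]
        missing += [l for l in model.label_names if l not in y_tbl.feature_names]
        if missing:
            raise ValidationError(
                f"dataset {k}: missing model feature(s)/label(s): {missing}"
            )
        x_tbl = x_tbl.select_features(model.feature_names)
        y_tbl = y_tbl.select_features(model.label_names)
        if config.scaler_fit == "independent":
            xs = apply_scaler(x_tbl, fit_scaler(x_tbl, model.scaler_x.method))
            ys = apply_scaler(y_tbl, fit_scaler(y_tbl, model.scaler_y.method))
        else:
            xs = apply_scaler(x_tbl, model.scaler_x)
            ys = apply_scaler(y_tbl, model.scaler_y)
        Y_pred = predict_matrix(model, xs.values)
        evals = evaluate_labels(model.label_names, ys.values, Y_pred)
        all_evals.append(evals)
        ds_dir = job_dir / f"validation_set_{k}"
        ds_dir.mkdir(exist_ok=True)
        metrics_frame(evals).to_csv(
            ds_dir / "metrics.csv", index=False, float_format=_CSV_FLOAT_FORMAT
        )
        auc_dir = ds_dir / "auc_dt"
        auc_dir.mkdir(exist_ok=True)
        for e in evals:
            auc_curve_frame(e).to_csv(
                auc_dir / f"{_safe_name(e.label_name)}.csv", index=False,
                float_format=_CSV_FLOAT_FORMAT,
            )
        log.append(f"validation set {k}: {x_tbl.n_samples} samples evaluated")
    (job_dir / "run.log").write_text("\n".join(log) + "\n")
    return job_dir, all_evals


def run_predict(
    config: ExperimentConfig,
    model_file: str | Path,
    data_csv: str | Path,
) -> tuple[Path, pd.DataFrame]:
    """Predict labels (normalized label space) for a new data table."""
    job_dir = _prepare_job_dir(config)
    _snapshot(config, job_dir)
    model = load_model(model_file)
    role = "imaging" if config.data_role == "imaging" else "omics"
    x_tbl = load_feature_table(data_csv, role)
    missing = [f for f in model.feature_names if f not in x_tbl.feature_names]
    if missing:
        raise ValidationError(f"input is missing model feature(s): {missing}")
    x_tbl = x_tbl.select_features(model.feature_names)
    if config.scaler_fit == "independent":
        xs = apply_scaler(x_tbl, fit_scaler(x_tbl, model.scaler_x.method))
    else:
        xs = apply_scaler(x_tbl, model.scaler_x)
    Y_pred = predict_matrix(model, xs.values)
    out = pd.DataFrame(Y_pred, index=x_tbl.sample_ids, columns=model.label_names)
    out.index.name = "Sample"
    out_path = job_dir / "predictions.csv"
    out.to_csv(out_path, float_format=_CSV_FLOAT_FORMAT)
    (job_dir / "run.log").write_text(
        f"mode=predict model={model_file}\n"
        f"predicted {out.shape[0]} samples x {out.shape[1]} labels\n"
    )
    return job_dir, out
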