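"""Regression model families mapping data features (X) to label features (Y).

Six families are supported: ordinary linear regression, LASSO, elastic net,
their multi-task (group-sparse) variants, and decision trees.  Linear
families fit all labels through one scikit-learn estimator (coefficient
matrix of shape n_labels × n_features); the decision-tree family fits one
regressor per label so that per-label feature importances are well defined.

Training always happens in normalized space: the caller passes the scaled
matrices and the fitted :class:`~imagene.data_io.ScalerParams` for both X
and Y, which travel with the model so Validate/Predict runs can reproduce
the transform.  Cross-validation folds are contiguous without shuffling by
default (opt-in seeded shuffling), scored by negative mean squared error.
"""

from __future__ import annotations

import io
import json
import pickle
import struct
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LinearRegression,
    MultiTaskElasticNet,
    MultiTaskLasso,
)
from sklearn.model_selection import KFold
from sklearn.multioutput import MultiOutputRegressor
from sklearn.tree import DecisionTreeRegressor

from .data_io import ConfigError, ScalerParams, ValidationError

MODEL_TYPES = (
    "linear",
    "lasso",
    "elastic_net",
    "multi_task_lasso",
    "multi_task_elastic_net",
    "decision_tree",
)

#: Families whose labels are fitted independently of one another; a
#: single-label refit of such a family reproduces the joint fit exactly.
PER_LABEL_INDEPENDENT = ("linear", "lasso", "elastic_net", "decision_tree")

#: Frozen default hyperparameters per family (unspecified parameters fall
#: back to these; anything else the user names is passed straight through).
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "linear": {},
    "lasso": {"alpha": 1.0, "tol": 1e-4, "max_iter": 1000},
    "elastic_net": {"alpha": 1.0, "l1_ratio": 0.5, "tol": 1e-4, "max_iter": 1000},
    "multi_task_lasso": {"alpha": 1.0, "tol": 1e-4, "max_iter": 1000},
    "multi_task_elastic_net": {
        "alpha": 1.0,
        "l1_ratio": 0.5,
        "tol": 1e-4,
        "max_iter": 1000,
    },
    "decision_tree": {},
}

_MODEL_FILE_MAGIC = b"IMAGENE-MODEL-v1\n"


@dataclass
class ModelSpec:
    """Which family to fit, with what hyperparameters, grid and CV plan."""

    model_type: str = "decision_tree"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    grid: dict[str, list[Any]] | None = None
    cv_folds: int = 2
    seed: int = 0
    shuffle_folds: bool = False

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ConfigError(
                f"unknown model type {self.model_type!r}; "
                f"choose from {MODEL_TYPES}"
            )
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds={self.cv_folds} must be >= 2")

    def resolved_params(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS[self.model_type])
        params.update(self.hyperparameters)
        return params


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to reapply it."""

    spec: ModelSpec
    estimator: Any                      # sklearn estimator (fitted)
    feature_names: list[str]
    label_names: list[str]
    scaler_x: ScalerParams
    scaler_y: ScalerParams
    cv_scores: np.ndarray               # per-fold negative MSE
    chosen_params: dict[str, Any]       # post grid search

    # -- weights -----------------------------------------------------------
    @property
    def is_tree(self) -> bool:
        return self.spec.model_type == "decision_tree"

    def coefficient_matrix(self) -> np.ndarray:
        """(n_labels × n_features) coefficients for linear families."""
        if self.is_tree:
            raise ConfigError("decision trees have importances, not coefficients")
        coef = np.atleast_2d(self.estimator.coef_)
        return coef

    def label_weights(self, label: str) -> np.ndarray:
        """Per-feature weights for one label: importances (tree, sum to 1)
        or signed coefficients (linear families)."""
        j = self.label_names.index(label)
        if self.is_tree:
            return self.estimator.estimators_[j].feature_importances_
        return self.coefficient_matrix()[j]

    def intercepts(self) -> np.ndarray:
        if self.is_tree:
            raise ConfigError("decision trees have no intercept")
        return np.atleast_1d(self.estimator.intercept_)


def _build_estimator(model_type: str, params: dict[str, Any], seed: int):
    p = dict(params)
    if model_type == "linear":
        return LinearRegression(**p)
    if model_type == "lasso":
        return Lasso(random_state=seed, **p)
    if model_type == "elastic_net":
        return ElasticNet(random_state=seed, **p)
    if model_type == "multi_task_lasso":
        return MultiTaskLasso(random_state=seed, **p)
    if model_type == "multi_task_elastic_net":
        return MultiTaskElasticNet(random_state=seed, **p)
    if model_type == "decision_tree":
        return MultiOutputRegressor(DecisionTreeRegressor(random_state=seed, **p))
    raise ConfigError(f"unknown model type {model_type!r}")


def _check_xy(spec: ModelSpec, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValidationError("X and Y must be 2-D matrices")
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must be row-aligned")
    if X.shape[1] == 0:
        raise ValidationError("no features to train on")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValidationError("NaNs in training data")
    if spec.model_type.startswith("multi_task") and Y.shape[1] < 2:
        raise ConfigError(
            f"{spec.model_type} requires at least 2 label columns, "
            f"got {Y.shape[1]}"
        )
    return X, Y


def fit_estimator(spec: ModelSpec, X: np.ndarray, Y: np.ndarray,
                  params: dict[str, Any] | None = None):
    """Fit a bare estimator (no scalers/metadata); used by refit loops."""
    X, Y = _check_xy(spec, X, Y)
    est = _build_estimator(
        spec.model_type, params if params is not None else spec.resolved_params(),
        spec.seed,
    )
    est.fit(X, Y)
    return est


def cross_validate(
    spec: ModelSpec, X: np.ndarray, Y: np.ndarray,
    params: dict[str, Any] | None = None,
) -> np.ndarray:
    """Per-fold negative MSE over a K-fold partition covering every row once."""
    X, Y = _check_xy(spec, X, Y)
    if spec.cv_folds > X.shape[0]:
        raise ConfigError(
            f"cv_folds={spec.cv_folds} exceeds n_rows={X.shape[0]}"
        )
    kf = KFold(
        n_splits=spec.cv_folds,
        shuffle=spec.shuffle_folds,
        random_state=spec.seed if spec.shuffle_folds else None,
    )
    use = params if params is not None else spec.resolved_params()
    scores = []
    for train_idx, val_idx in kf.split(X):
        est = _build_estimator(spec.model_type, use, spec.seed)
        est.fit(X[train_idx], Y[train_idx])
        pred = np.atleast_2d(est.predict(X[val_idx]))
        if pred.shape != Y[val_idx].shape:
            pred = pred.reshape(Y[val_idx].shape)
        scores.append(-float(np.mean((Y[val_idx] - pred) ** 2)))
    return np.asarray(scores)


def grid_search(
    spec: ModelSpec, X: np.ndarray, Y: np.ndarray
) -> tuple[dict[str, Any], list[tuple[dict[str, Any], float]]]:
    """Exhaustive search over the grid's candidate product.

    Returns (winning params, log of (candidate, mean CV negative MSE)).
    The winner maximizes the mean negative MSE; ties keep the first
    candidate in grid order.
    """
    if not spec.grid:
        raise ConfigError("grid_search requires a non-empty grid")
    for name, cands in spec.grid.items():
        if not cands:
            raise ConfigError(f"empty candidate list for grid parameter {name!r}")
    names = list(spec.grid.keys())
    log: list[tuple[dict[str, Any], float]] = []
    best_params: dict[str, Any] | None = None
    best_score = -np.inf
    for combo in product(*(spec.grid[n] for n in names)):
        candidate = spec.resolved_params()
        candidate.update(dict(zip(names, combo)))
        score = float(np.mean(cross_validate(spec, X, Y, params=candidate)))
        log.append((dict(zip(names, combo)), score))
        if score > best_score:
            best_score = score
            best_params = candidate
    assert best_params is not None
    return best_params, log


def train(
    spec: ModelSpec,
    X: np.ndarray,
    Y: np.ndarray,
    feature_names: list[str],
    label_names: list[str],
    scaler_x: ScalerParams,
    scaler_y: ScalerParams,
    use_grid: bool = False,
) -> TrainedModel:
    """Fit a model on normalized training data, with optional grid search.

    CV scores are computed with the final (possibly grid-chosen)
    hyperparameters, then the model is refit on the full training set.
    Deterministic given the spec seed.
    """
    X, Y = _check_xy(spec, X, Y)
    if len(feature_names) != X.shape[1]:
        raise ValidationError("feature_names length does not match X")
    if len(label_names) != Y.shape[1]:
        raise ValidationError("label_names length does not match Y")
    if use_grid:
        chosen, _ = grid_search(spec, X, Y)
    else:
        chosen = spec.resolved_params()
    cv_scores = cross_validate(spec, X, Y, params=chosen)
    est = fit_estimator(spec, X, Y, params=chosen)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(feature_names),
        label_names=list(label_names),
        scaler_x=scaler_x,
        scaler_y=scaler_y,
        cv_scores=cv_scores,
        chosen_params=chosen,
    )


def predict_matrix(m: TrainedModel, X_scaled: np.ndarray) -> np.ndarray:
    """Predict (normalized label space) from an already-scaled X matrix."""
    X_scaled = np.asarray(X_scaled, dtype=float)
    if X_scaled.shape[1] != len(m.feature_names):
        raise ValidationError(
            f"expected {len(m.feature_names)} feature columns, "
            f"got {X_scaled.shape[1]}"
        )
    pred = np.asarray(m.estimator.predict(X_scaled), dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    return pred


def predict(m: TrainedModel, x_new, scaler_fit: str = "independent") -> np.ndarray:
    """Predict labels for a :class:`FeatureTable` given in original units.

    Scaling is applied internally: ``independent`` refits the stored scaler
    method on the new data (the pipeline's default normalization policy);
    ``train_only`` reapplies the training-set statistics.  Output is in
    normalized label space, one column per label.
    """
    from .data_io import apply_scaler, fit_scaler  # local: avoid cycle at import

    missing = [f for f in m.feature_names if f not in x_new.feature_names]
    if missing:
        raise ValidationError(f"input is missing model feature(s): {missing}")
    x_new = x_new.select_features(m.feature_names)
    if scaler_fit == "independent":
        x_scaled = apply_scaler(x_new, fit_scaler(x_new, m.scaler_x.method))
    elif scaler_fit == "train_only":
        x_scaled = apply_scaler(x_new, m.scaler_x)
    else:
        raise ConfigError(f"unknown scaler_fit policy {scaler_fit!r}")
    return predict_matrix(m, x_scaled.values)


# ---------------------------------------------------------------------------
# Persistence: JSON metadata header + pickled estimator payload
# ---------------------------------------------------------------------------

class ModelFileError(RuntimeError):
    """Model file is missing, corrupt, or from an incompatible version."""


def save_model(m: TrainedModel, path: str | Path) -> None:
    header = {
        "model_type": m.spec.model_type,
        "hyperparameters": m.spec.hyperparameters,
        "grid": m.spec.grid,
        "cv_folds": m.spec.cv_folds,
        "seed": m.spec.seed,
        "shuffle_folds": m.spec.shuffle_folds,
        "feature_names": m.feature_names,
        "label_names": m.label_names,
        "scaler_x": m.scaler_x.as_dict(),
        "scaler_y": m.scaler_y.as_dict(),
        "cv_scores": m.cv_scores.tolist(),
        "chosen_params": m.chosen_params,
    }
    header_bytes = json.dumps(header, sort_keys=True).encode("utf-8")
    payload = pickle.dumps(m.estimator, protocol=4)
    with open(path, "wb") as fh:
        fh.write(_MODEL_FILE_MAGIC)
        fh.write(struct.pack("<Q", len(header_bytes)))
        fh.write(header_bytes)
        fh.write(payload)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise ModelFileError(f"model file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(len(_MODEL_FILE_MAGIC))
        if magic != _MODEL_FILE_MAGIC:
            raise ModelFileError(f"{path}: not a recognized model file")
        try:
            (header_len,) = struct.unpack("<Q", fh.read(8))
            header = json.loads(fh.read(header_len).decode("utf-8"))
            estimator = pickle.load(fh)
        except Exception as exc:  # noqa: BLE001 - surface as one error type
            raise ModelFileError(f"{path}: corrupt model file ({exc})") from exc
    spec = ModelSpec(
        model_type=header["model_type"],
        hyperparameters=header["hyperparameters"],
        grid=header["grid"],
        cv_folds=header["cv_folds"],
        seed=header["seed"],
        shuffle_folds=header.get("shuffle_folds", False),
    )
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=header["feature_names"],
        label_names=header["label_names"],
        scaler_x=ScalerParams.from_dict(header["scaler_x"]),
        scaler_y=ScalerParams.from_dict(header["scaler_y"]),
        cv_scores=np.asarray(header["cv_scores"], dtype=float),
        chosen_params=header["chosen_params"],
    )
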