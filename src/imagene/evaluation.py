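"""Per-label model scoring: v = RMSE/STDEV, R² two ways, and the dt AUC sweep.

For every label y the test residuals give MSE and RMSE; dividing RMSE by the
population standard deviation of the observed values yields the ratio

    v = RMSE(y) / std(y) = sqrt(SSL / SST),

where SSL is the residual and SST the total sum of squares.  Since by
definition R² = 1 − SSL/SST, the identity

    R² = 1 − v²

lets v and R² be reported as two views of the same quantity; R² is also
computed directly from the sums of squares as a consistency check.  v = 1
means the model is no better than predicting the label mean; v > 1 (R² < 0)
means it is worse.  All of this requires the population (ddof=0) standard
deviation, which is used throughout.

To judge a regression model as a high/low classifier, observed label values
are min–max rescaled to [0, 1] and binarized at each decision threshold
dt ∈ {0.1, …, 1.0} (value < dt → 0, value ≥ dt → 1); predictions stay
continuous and serve as ranking scores for a Mann–Whitney AUC.  Thresholds
where the binarized labels are all one class have no defined AUC and are
reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .modeling import TrainedModel

#: Default decision-threshold grid.
DEFAULT_DT_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class DtGrid:
    """Strictly increasing decision thresholds within [0, 1]."""

    thresholds: tuple[float, ...] = DEFAULT_DT_GRID

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if not t:
            raise ValueError("empty dt grid")
        if any(not (0.0 <= x <= 1.0) for x in t):
            raise ValueError("dt values must lie in [0, 1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("dt grid must be strictly increasing")
        self.thresholds = t


@dataclass
class LabelEvaluation:
    """All per-label scores for one label on one evaluation set."""

    label_name: str
    mse: float
    rmse: float
    stdev: float
    ssl: float
    sst: float
    v: float                 # NaN when y_obs is constant
    r2_direct: float         # NaN when y_obs is constant
    r2_identity: float       # NaN when y_obs is constant
    auc_curve: list[tuple[float, float]] = field(default_factory=list)
    # (dt, auc); auc is NaN where undefined (single-class binarization)

    @property
    def defined(self) -> bool:
        """False when y_obs was constant, leaving v and R² undefined."""
        return np.isfinite(self.v)

    @property
    def headline_auc(self) -> float:
        """Max defined AUC over the dt grid (NaN if none is defined)."""
        defined = [a for _, a in self.auc_curve if np.isfinite(a)]
        return max(defined) if defined else float("nan")

    def best_dt_range(self) -> list[float]:
        """Thresholds achieving the headline AUC (rounded to 1e-12 ties)."""
        h = self.headline_auc
        if not np.isfinite(h):
            return []
        return [dt for dt, a in self.auc_curve if np.isfinite(a) and abs(a - h) < 1e-12]


def score_label(
    label_name: str, y_obs: np.ndarray, y_pred: np.ndarray
) -> LabelEvaluation:
    """MSE, RMSE, STDEV, v and both R² computations for one label."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    n = y_obs.size
    if n < 2:
        raise ValueError("need at least 2 observations to score a label")
    resid = y_obs - y_pred
    ssl = float(np.sum(resid**2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    mse = ssl / n
    rmse = float(np.sqrt(mse))
    stdev = float(np.sqrt(sst / n))  # population convention
    if sst == 0.0:
        v = r2d = r2i = float("nan")
    else:
        v = rmse / stdev
        r2d = 1.0 - ssl / sst
        r2i = 1.0 - v**2
    return LabelEvaluation(
        label_name=label_name,
        mse=mse,
        rmse=rmse,
        stdev=stdev,
        ssl=ssl,
        sst=sst,
        v=v,
        r2_direct=r2d,
        r2_identity=r2i,
    )


def binarize(y: np.ndarray, dt: float) -> np.ndarray:
    """0/1 vector: value < dt → 0, value ≥ dt → 1."""
    y = np.asarray(y, dtype=float)
    return (y >= dt).astype(int)


def auc(binary_labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC; ties credited 0.5.

    Returns NaN when the labels are all one class.
    """
    binary_labels = np.asarray(binary_labels)
    scores = np.asarray(scores, dtype=float)
    if binary_labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(binary_labels.sum())
    n_neg = binary_labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    u = ranks[binary_labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rescale_for_sweep(
    y_obs: np.ndarray, y_pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min–max map y_obs onto [0, 1]; push y_pred through the same map.

    The dt grid lives in [0, 1] while the modeling scaler may be the
    standard scaler, so the sweep rescales independently of model space.
    The shared affine map preserves score ranking, hence every AUC.
    Constant y_obs maps to all-0.5 (no threshold separates it anyway).
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    lo, hi = y_obs.min(), y_obs.max()
    if hi == lo:
        return np.full_like(y_obs, 0.5), np.full_like(y_pred, 0.5)
    return (y_obs - lo) / (hi - lo), (y_pred - lo) / (hi - lo)


def auc_sweep(
    y_obs: np.ndarray, y_pred: np.ndarray, grid: DtGrid | None = None
) -> list[tuple[float, float]]:
    """One (dt, AUC-or-NaN) point per grid threshold."""
    grid = grid or DtGrid()
    obs01, pred01 = rescale_for_sweep(y_obs, y_pred)
    curve = []
    for dt in grid.thresholds:
        curve.append((dt, auc(binarize(obs01, dt), pred01)))
    return curve


def evaluate_labels(
    label_names: list[str],
    Y_obs: np.ndarray,
    Y_pred: np.ndarray,
    grid: DtGrid | None = None,
) -> list[LabelEvaluation]:
    """Score every label and attach its AUC-vs-dt curve."""
    Y_obs = np.atleast_2d(np.asarray(Y_obs, dtype=float))
    Y_pred = np.atleast_2d(np.asarray(Y_pred, dtype=float))
    if Y_obs.shape != Y_pred.shape or Y_obs.shape[1] != len(label_names):
        raise ValueError("label names and matrices are inconsistent")
    out = []
    for j, name in enumerate(label_names):
        ev = score_label(name, Y_obs[:, j], Y_pred[:, j])
        ev.auc_curve = auc_sweep(Y_obs[:, j], Y_pred[:, j], grid)
        out.append(ev)
    return out


def metrics_frame(evals: list[LabelEvaluation]) -> pd.DataFrame:
    """Per-label metrics table (one row per label)."""
    return pd.DataFrame(
        [
            {
                "label": e.label_name,
                "MSE": e.mse,
                "RMSE": e.rmse,
                "STDEV": e.stdev,
                "v": e.v,
                "R2_direct": e.r2_direct,
                "R2_identity": e.r2_identity,
                "AUC_max": e.headline_auc,
                "best_dt_range": _format_dt_range(e.best_dt_range()),
            }
            for e in evals
        ]
    )


def auc_curve_frame(e: LabelEvaluation) -> pd.DataFrame:
    return pd.DataFrame(e.auc_curve, columns=["dt", "AUC"])


def _format_dt_range(dts: list[float]) -> str:
    if not dts:
        return ""
    if len(dts) == 1:
        return f"{dts[0]:g}"
    return f"[{dts[0]:g}, {dts[-1]:g}]"


def export_feature_weights(m: TrainedModel) -> pd.DataFrame:
    """Per-(label, feature) weight table.

    Tree models report feature importances (nonnegative, summing to 1 per
    label); linear families report signed coefficients.
    """
    rows = []
    kind = "importance" if m.is_tree else "coefficient"
    for label in m.label_names:
        w = m.label_weights(label)
        for fname, wi in zip(m.feature_names, w):
            rows.append(
                {"label": label, "feature": fname, "weight": float(wi), "kind": kind}
            )
    return pd.DataFrame(rows)
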