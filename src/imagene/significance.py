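"""Permutation tests for confidently predicted labels.

Only labels clearing the test-phase gate — headline AUC > 0.9 AND R² > 0.25,
both strict — are permutation-tested; the gate keeps the expensive refits
focused on labels the model already predicts well.  Each permutation
shuffles that label's training values across samples, refits the model, and
re-evaluates on the untouched test split.  The p-values are plain counts,

    p_auc = #{AUC_perm >= AUC_test} / n_perm      (R² analogous),

so p = 0 is attainable when the observed statistic beats every permutation;
an opt-in ``smoothed`` flag gives the (count+1)/(n_perm+1) variant instead.

For families whose labels are fitted independently (linear, lasso,
elastic net, decision tree) the refit is done on the permuted label column
alone — exactly equivalent to refitting the full multi-output model and
about n_labels times faster; multi-task families refit the whole coupled
model with the one column permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ConfigError
from .evaluation import DtGrid, LabelEvaluation, auc_sweep, score_label
from .modeling import PER_LABEL_INDEPENDENT, ModelSpec, fit_estimator

#: Test-phase gate thresholds (strict inequalities).
GATE_AUC = 0.9
GATE_R2 = 0.25


@dataclass
class PermutationResult:
    label_name: str
    auc_test: float
    r2_test: float
    n_permutations: int
    auc_perm: np.ndarray
    r2_perm: np.ndarray
    p_auc: float
    p_r2: float

    def to_frame(self) -> pd.DataFrame:
        """'validation permuts' table: one row per permutation."""
        return pd.DataFrame(
            {
                "permutation": np.arange(1, self.n_permutations + 1),
                "AUC_perm": self.auc_perm,
                "R2_perm": self.r2_perm,
            }
        )


def is_gated(e: LabelEvaluation) -> bool:
    return (
        e.defined
        and np.isfinite(e.headline_auc)
        and e.headline_auc > GATE_AUC
        and e.r2_direct > GATE_R2
    )


def gate_labels(evals: list[LabelEvaluation]) -> list[str]:
    """Labels whose headline AUC and test R² clear the strict gate."""
    return [e.label_name for e in evals if is_gated(e)]


def permutation_test(
    spec: ModelSpec,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    y_obs_test: np.ndarray,
    label: str,
    label_names: list[str],
    n_perm: int = 100,
    seed: int = 0,
    grid: DtGrid | None = None,
    params: dict | None = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Permute one label's training values, refit, re-evaluate on test.

    ``params`` carries the finalized (possibly grid-chosen) hyperparameters
    so permutation refits match the observed model's settings.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm={n_perm} must be >= 1")
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    j = label_names.index(label)
    rng = np.random.default_rng(seed)

    independent = spec.model_type in PER_LABEL_INDEPENDENT

    def fit_and_score(y_col_perm: np.ndarray) -> tuple[float, float]:
        if independent:
            est = fit_estimator(spec, X_train, y_col_perm[:, None], params=params)
            pred = np.asarray(est.predict(X_test), dtype=float).reshape(-1)
        else:
            Y_perm = Y_train.copy()
            Y_perm[:, j] = y_col_perm
            est = fit_estimator(spec, X_train, Y_perm, params=params)
            pred = np.asarray(est.predict(X_test), dtype=float)[:, j]
        ev = score_label(label, y_obs_test, pred)
        curve = auc_sweep(y_obs_test, pred, grid)
        defined = [a for _, a in curve if np.isfinite(a)]
        return (max(defined) if defined else float("nan")), ev.r2_direct

    auc_test, r2_test = fit_and_score(Y_train[:, j])

    auc_perm = np.empty(n_perm)
    r2_perm = np.empty(n_perm)
    for k in range(n_perm):
        auc_perm[k], r2_perm[k] = fit_and_score(rng.permutation(Y_train[:, j]))

    def count_p(perm: np.ndarray, obs: float) -> float:
        c = int(np.sum(perm >= obs))
        if smoothed:
            return (c + 1) / (n_perm + 1)
        return c / n_perm

    return PermutationResult(
        label_name=label,
        auc_test=auc_test,
        r2_test=r2_test,
        n_permutations=n_perm,
        auc_perm=auc_perm,
        r2_perm=r2_perm,
        p_auc=count_p(auc_perm, auc_test),
        p_r2=count_p(r2_perm, r2_test),
    )


def summary_frame(results: list[PermutationResult]) -> pd.DataFrame:
    """Per-label permutation p-value summary."""
    return pd.DataFrame(
        [
            {
                "label": r.label_name,
                "AUC_test": r.auc_test,
                "R2_test": r.r2_test,
                "n_permutations": r.n_permutations,
                "p_AUC": r.p_auc,
                "p_R2": r.p_r2,
            }
            for r in results
        ]
    )
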