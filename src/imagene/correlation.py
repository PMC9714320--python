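"""Imaging ↔ omics correlation testing, multiple-testing control and filtering.

Every (imaging feature, omics feature) pair gets a Pearson or Spearman
coefficient with a two-sided p-value; the pooled p-values are adjusted with
one of the standard family-wise / FDR procedures, and a pair survives when
|r| exceeds the coefficient threshold AND the adjusted p falls below the
significance threshold.  A coefficient threshold of −1.0 disables the filter
entirely and hands every feature to the modeling stage.

Correlation is computed on the raw (non-normalized) matched tables; scaling
is a monotone affine map so Pearson/Spearman would be unchanged anyway, but
the contract keeps the stage order explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .data_io import ConfigError, FeatureTable

CORRELATION_METHODS = ("pearson", "spearman")

#: Accepted adjustment names (R's p.adjust vocabulary); ``fdr`` aliases BH.
ADJUSTMENT_METHODS = ("holm", "hochberg", "hommel", "bonferroni", "BH", "BY", "fdr")

_STATSMODELS_NAME = {
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "bonferroni": "bonferroni",
    "BH": "fdr_bh",
    "BY": "fdr_by",
    "fdr": "fdr_bh",
}


@dataclass
class CorrelationResult:
    """Coefficients, p-values and the surviving feature subsets."""

    method: str
    imaging_features: list[str]
    omics_features: list[str]
    r: np.ndarray        # (n_imaging, n_omics)
    p_raw: np.ndarray
    p_adj: np.ndarray
    correction_method: str
    coefficient_threshold: float
    p_threshold: float
    surviving_imaging: list[str]
    surviving_omics: list[str]
    surviving_pairs: list[tuple[str, str]]

    @property
    def disabled(self) -> bool:
        return self.coefficient_threshold == -1.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (imaging, omics) pair."""
        rows = []
        surv = set(self.surviving_pairs)
        for i, fi in enumerate(self.imaging_features):
            for j, fo in enumerate(self.omics_features):
                rows.append(
                    {
                        "feature_imaging": fi,
                        "feature_omics": fo,
                        "r": self.r[i, j],
                        "p_raw": self.p_raw[i, j],
                        "p_adj": self.p_adj[i, j],
                        "survives": (fi, fo) in surv,
                    }
                )
        return pd.DataFrame(rows)


def correlate(
    x: FeatureTable, y: FeatureTable, method: str = "spearman"
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient and two-sided p-value for every (x-feature, y-feature) pair.

    Spearman is Pearson on average ranks; p-values come from the
    t-distribution on r with n − 2 degrees of freedom.  A zero-variance
    feature yields r = 0, p = 1 for its pairs, with a warning.
    """
    if method not in CORRELATION_METHODS:
        raise ConfigError(f"unknown correlation method {method!r}")
    if x.sample_ids != y.sample_ids:
        raise ConfigError("tables must be sample-matched before correlation")
    n = x.n_samples
    if n < 3:
        raise ConfigError(f"need at least 3 samples for correlation, got {n}")

    a = x.values.astype(float)
    b = y.values.astype(float)
    if method == "spearman":
        a = stats.rankdata(a, axis=0)  # average-rank ties
        b = stats.rankdata(b, axis=0)

    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    sa = np.sqrt((a_c**2).sum(axis=0))
    sb = np.sqrt((b_c**2).sum(axis=0))
    degenerate_a = sa == 0
    degenerate_b = sb == 0
    if degenerate_a.any() or degenerate_b.any():
        bad = [f for f, d in zip(x.feature_names, degenerate_a) if d] + [
            f for f, d in zip(y.feature_names, degenerate_b) if d
        ]
        warnings.warn(
            f"zero-variance feature(s), correlation recorded as 0: {bad}",
            stacklevel=2,
        )
    denom = np.outer(np.where(degenerate_a, 1.0, sa), np.where(degenerate_b, 1.0, sb))
    r = (a_c.T @ b_c) / denom
    r = np.clip(r, -1.0, 1.0)
    r[degenerate_a, :] = 0.0
    r[:, degenerate_b] = 0.0

    # two-sided p via t = r * sqrt((n-2) / (1-r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[degenerate_a, :] = 1.0
    p[:, degenerate_b] = 1.0
    return r, p


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Adjust a flat vector of p-values; output order matches input order."""
    if method not in ADJUSTMENT_METHODS:
        raise ConfigError(
            f"unknown correction method {method!r}; "
            f"choose from {ADJUSTMENT_METHODS}"
        )
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(
        p.ravel(), alpha=0.05, method=_STATSMODELS_NAME[method]
    )
    return np.minimum(adj, 1.0).reshape(p.shape)


def filter_by_correlation(
    x: FeatureTable,
    y: FeatureTable,
    method: str = "spearman",
    coefficient_threshold: float = 0.5,
    correction_method: str = "BH",
    p_threshold: float = 0.05,
) -> CorrelationResult:
    """Run the full correlation stage: test, adjust, threshold.

    A pair survives iff |r| > ``coefficient_threshold`` and adjusted
    p < ``p_threshold`` (both strict); a feature survives iff it belongs to
    at least one surviving pair.  ``coefficient_threshold = -1.0`` disables
    filtering: every feature survives regardless of p-values.
    """
    r, p_raw = correlate(x, y, method)
    p_adj = adjust_pvalues(p_raw.ravel(), correction_method).reshape(p_raw.shape)

    if coefficient_threshold == -1.0:
        surviving_imaging = list(x.feature_names)
        surviving_omics = list(y.feature_names)
        pairs = [(fi, fo) for fi in x.feature_names for fo in y.feature_names]
    else:
        mask = (np.abs(r) > coefficient_threshold) & (p_adj < p_threshold)
        pairs = [
            (x.feature_names[i], y.feature_names[j])
            for i, j in np.argwhere(mask)
        ]
        img_set = {fi for fi, _ in pairs}
        omi_set = {fo for _, fo in pairs}
        surviving_imaging = [f for f in x.feature_names if f in img_set]
        surviving_omics = [f for f in y.feature_names if f in omi_set]

    return CorrelationResult(
        method=method,
        imaging_features=list(x.feature_names),
        omics_features=list(y.feature_names),
        r=r,
        p_raw=p_raw,
        p_adj=p_adj,
        correction_method=correction_method,
        coefficient_threshold=coefficient_threshold,
        p_threshold=p_threshold,
        surviving_imaging=surviving_imaging,
        surviving_omics=surviving_omics,
        surviving_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Heat-map ordering
# ---------------------------------------------------------------------------

def _profile_distance(m: np.ndarray) -> np.ndarray:
    """Condensed distance between rows: 1 − |Pearson r| of row profiles.

    Constant rows have an undefined profile correlation; their distance to
    every other row is taken as 1 (maximal dissimilarity).
    """
    k = m.shape[0]
    c = m - m.mean(axis=1, keepdims=True)
    s = np.sqrt((c**2).sum(axis=1))
    const = s == 0
    denom = np.outer(np.where(const, 1.0, s), np.where(const, 1.0, s))
    rr = (c @ c.T) / denom
    rr = np.clip(rr, -1.0, 1.0)
    d = 1.0 - np.abs(rr)
    d[const, :] = 1.0
    d[:, const] = 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return squareform(d, checks=False)


def cluster_order(
    m: np.ndarray,
) -> tuple[list[int], list[int], tuple[np.ndarray | None, np.ndarray | None]]:
    """Leaf orders for a hierarchically clustered heat map of ``m``.

    Rows and columns are clustered separately by average-linkage
    agglomeration on the 1 − |r| profile-similarity distance.  Returns
    (row order, column order, (row linkage, column linkage)); a single
    row/column yields the identity order with a ``None`` linkage.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("coefficient matrix must be finite")

    def one_axis(mat: np.ndarray) -> tuple[list[int], np.ndarray | None]:
        if mat.shape[0] == 1:
            return [0], None
        z = average(_profile_distance(mat))
        return leaves_list(z).tolist(), z

    row_order, row_z = one_axis(m)
    col_order, col_z = one_axis(m.T)
    return row_order, col_order, (row_z, col_z)
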