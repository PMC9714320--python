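"""Correlation coefficients, p-value adjustment, filtering and clustering."""

import numpy as np
import pytest
from scipy import stats

from imagene import (
    ConfigError,
    FeatureTable,
    adjust_pvalues,
    cluster_order,
    correlate,
    filter_by_correlation,
)
from imagene.correlation import _profile_distance
from scipy.spatial.distance import squareform


def _tables(rng, n=20, p=4, q=5):
    x = FeatureTable(
        [f"S{i}" for i in range(n)],
        [f"F{j}" for j in range(p)],
        rng.normal(size=(n, p)),
        "imaging",
    )
    y = FeatureTable(
        list(x.sample_ids),
        [f"G{j}" for j in range(q)],
        rng.normal(size=(n, q)),
        "omics",
    )
    return x, y


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def pearson_oracle(a, b):
    """Closed-form covariance / (sigma_a * sigma_b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return cov / (a.std(ddof=0) * b.std(ddof=0))


def adjust_oracle(p, method):
    """Step-up / step-down formulas, straight from their definitions."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj = np.empty(m)
    if method == "bonferroni":
        adj_sorted = np.minimum(m * ps, 1.0)
    elif method == "holm":  # step-down max of (m - j + 1) p_(j)
        vals = (m - np.arange(m)) * ps
        adj_sorted = np.minimum(np.maximum.accumulate(vals), 1.0)
    elif method == "hochberg":  # step-up min of (m - j + 1) p_(j)
        vals = (m - np.arange(m)) * ps
        adj_sorted = np.minimum(np.minimum.accumulate(vals[::-1])[::-1], 1.0)
    elif method == "BH":  # step-up min of p_(j) m / j
        vals = ps * m / (np.arange(m) + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(vals[::-1])[::-1], 1.0)
    elif method == "BY":
        c = np.sum(1.0 / (np.arange(m) + 1))
        vals = ps * m * c / (np.arange(m) + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(vals[::-1])[::-1], 1.0)
    else:
        raise ValueError(method)
    adj[order] = adj_sorted
    return adj


class TestCorrelate:
    def test_self_and_negated(self, rng):
        x, _ = _tables(rng)
        y = FeatureTable(
            list(x.sample_ids), ["same", "neg"],
            np.column_stack([x.values[:, 0], -x.values[:, 0]]),
            "omics",
        )
        r, p = correlate(x, y, "pearson")
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)
        assert p[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_matches_closed_form(self, rng):
        x, y = _tables(rng, n=15)
        r, _ = correlate(x, y, "pearson")
        for i in range(x.n_features):
            for j in range(y.n_features):
                assert r[i, j] == pytest.approx(
                    pearson_oracle(x.values[:, i], y.values[:, j]), abs=1e-12
                )

    def test_spearman_is_pearson_on_ranks(self, rng):
        x, y = _tables(rng, n=12)
        # introduce ties
        x.values[:4, 0] = 1.0
        r, _ = correlate(x, y, "spearman")
        for i in range(x.n_features):
            for j in range(y.n_features):
                ra = stats.rankdata(x.values[:, i])
                rb = stats.rankdata(y.values[:, j])
                assert r[i, j] == pytest.approx(pearson_oracle(ra, rb), abs=1e-12)

    def test_spearman_monotone_invariance(self, rng):
        x, _ = _tables(rng, n=10, p=1)
        y = FeatureTable(
            list(x.sample_ids), ["expx"], np.exp(x.values[:, :1]), "omics"
        )
        r, _ = correlate(x, y, "spearman")
        assert r[0, 0] == pytest.approx(1.0)

    def test_zero_variance_feature(self, rng):
        x, y = _tables(rng, n=8, p=2)
        x.values[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = correlate(x, y, "pearson")
        assert np.all(r[1, :] == 0) and np.all(p[1, :] == 1)

    def test_too_few_samples(self, rng):
        x, y = _tables(rng, n=2)
        with pytest.raises(ConfigError):
            correlate(x, y, "pearson")

    def test_pvalues_match_scipy(self, rng):
        x, y = _tables(rng, n=25, p=3, q=3)
        for method in ("pearson", "spearman"):
            r, p = correlate(x, y, method)
            for i in range(3):
                for j in range(3):
                    if method == "pearson":
                        ref = stats.pearsonr(x.values[:, i], y.values[:, j])
                    else:
                        ref = stats.spearmanr(x.values[:, i], y.values[:, j])
                    assert r[i, j] == pytest.approx(ref.statistic, abs=1e-12)
                    assert p[i, j] == pytest.approx(ref.pvalue, rel=1e-6)


class TestAdjustPvalues:
    def test_bonferroni_example(self):
        assert adjust_pvalues(np.array([0.01] * 5), "bonferroni")[0] == pytest.approx(0.05)

    def test_single_p_unchanged(self):
        for method in ("holm", "hochberg", "hommel", "bonferroni", "BH", "BY", "fdr"):
            assert adjust_pvalues(np.array([0.031]), method)[0] == pytest.approx(0.031)

    def test_bh_stepup_example(self):
        out = adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]), "BH")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("method", ["bonferroni", "holm", "hochberg", "BH", "BY"])
    def test_matches_bruteforce_oracle(self, method, rng):
        for _ in range(40):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(
                adjust_pvalues(p, method), adjust_oracle(p, method), atol=1e-12
            )

    @pytest.mark.parametrize(
        "method", ["bonferroni", "holm", "hochberg", "hommel", "BH", "BY"]
    )
    def test_monotone(self, method, rng):
        p = rng.uniform(size=30)
        adj = adjust_pvalues(p, method)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_adjusted_at_least_raw_for_fwe(self, rng):
        p = rng.uniform(size=20)
        for method in ("bonferroni", "holm"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-12)

    def test_fdr_aliases_bh(self, rng):
        p = rng.uniform(size=17)
        np.testing.assert_array_equal(
            adjust_pvalues(p, "fdr"), adjust_pvalues(p, "BH")
        )

    def test_hommel_worked_example(self):
        # classic 9-p-value example; reference values from R's p.adjust(..., "hommel")
        p = np.array(
            [0.0001, 0.0004, 0.0019, 0.0095, 0.0201, 0.0278, 0.0298, 0.0344, 0.0459]
        )
        expected = np.array(
            [0.0009, 0.0032, 0.0133, 0.0430, 0.0459, 0.0459, 0.0459, 0.0459, 0.0459]
        )
        np.testing.assert_allclose(adjust_pvalues(p, "hommel"), expected, atol=1e-4)

    def test_unknown_method(self):
        with pytest.raises(ConfigError):
            adjust_pvalues(np.array([0.5]), "sidak")


class TestFilter:
    def _planted(self, rng):
        x, y = _tables(rng, n=40, p=3, q=4)
        y.values[:, 0] = x.values[:, 0] * 2 + rng.normal(scale=0.2, size=40)
        return x, y

    def test_pair_semantics(self, rng):
        x, y = self._planted(rng)
        res = filter_by_correlation(x, y, "pearson", 0.5, "BH", 0.05)
        assert ("F0", "G0") in res.surviving_pairs
        assert "F0" in res.surviving_imaging and "G0" in res.surviving_omics
        for fi, fo in res.surviving_pairs:
            i = res.imaging_features.index(fi)
            j = res.omics_features.index(fo)
            assert abs(res.r[i, j]) > 0.5 and res.p_adj[i, j] < 0.05

    def test_disable_switch_passes_everything(self, rng):
        x, y = _tables(rng, n=10)
        res = filter_by_correlation(x, y, "pearson", -1.0, "BH", 0.05)
        assert res.surviving_imaging == x.feature_names
        assert res.surviving_omics == y.feature_names
        assert len(res.surviving_pairs) == x.n_features * y.n_features

    def test_high_r_low_significance_fails(self, rng):
        # n=5: |r|=0.9 cannot clear BH-adjusted p < 0.05 over 20 tests
        x, y = _tables(rng, n=5, p=4, q=5)
        res = filter_by_correlation(x, y, "pearson", 0.5, "bonferroni", 1e-6)
        assert not res.surviving_pairs

    def test_monotone_shrinkage(self, rng):
        x, y = self._planted(rng)
        lo = filter_by_correlation(x, y, "pearson", 0.3, "BH", 0.05)
        hi = filter_by_correlation(x, y, "pearson", 0.7, "BH", 0.05)
        assert set(hi.surviving_pairs) <= set(lo.surviving_pairs)

    def test_invariants(self, rng):
        x, y = _tables(rng, n=30)
        res = filter_by_correlation(x, y, "spearman", 0.5, "BH", 0.05)
        assert np.all(np.abs(res.r) <= 1)
        assert np.all((res.p_raw >= 0) & (res.p_raw <= 1))
        assert np.all((res.p_adj >= 0) & (res.p_adj <= 1))
        assert set(res.surviving_imaging) <= set(res.imaging_features)


class TestClusterOrder:
    def test_identical_rows_adjacent(self, rng):
        m = rng.normal(size=(4, 6))
        m[2] = m[0]
        rows, _, _ = cluster_order(m)
        assert abs(rows.index(0) - rows.index(2)) == 1

    def test_permutation_invariant(self, rng):
        m = rng.normal(size=(5, 7))
        rows, cols, _ = cluster_order(m)
        assert sorted(rows) == list(range(5))
        assert sorted(cols) == list(range(7))

    def test_single_row_identity(self, rng):
        rows, cols, (rz, _) = cluster_order(rng.normal(size=(1, 4)))
        assert rows == [0] and rz is None

    def test_merge_order_matches_bruteforce_agglomeration(self, rng):
        m = rng.normal(size=(4, 5))
        d = squareform(_profile_distance(m))
        # brute-force average-linkage on the same distances
        clusters = {i: [i] for i in range(4)}
        merges = []
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for ai in range(len(keys)):
                for bi in range(ai + 1, len(keys)):
                    a, b = keys[ai], keys[bi]
                    dist = np.mean(
                        [d[i, j] for i in clusters[a] for j in clusters[b]]
                    )
                    if best is None or dist < best[0]:
                        best = (dist, a, b)
            dist, a, b = best
            merges.append((frozenset(clusters[a] + clusters[b]), dist))
            new_key = max(clusters) + 1
            clusters[new_key] = clusters.pop(a) + clusters.pop(b)
        _, _, (rz, _) = cluster_order(m)
        # reconstruct scipy's merge sets
        members = {i: [i] for i in range(4)}
        for k, (a, b, h, _) in enumerate(rz):
            members[4 + k] = members[int(a)] + members[int(b)]
            assert frozenset(members[4 + k]) == merges[k][0]
            assert h == pytest.approx(merges[k][1], abs=1e-12)
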