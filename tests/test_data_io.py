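"""Loading, matching, screening, splitting and scaling of feature tables."""

import numpy as np
import pytest

from imagene import (
    ConfigError,
    FeatureTable,
    SplitSpec,
    ValidationError,
    apply_scaler,
    fit_scaler,
    invert_scaler,
    load_feature_table,
    match_samples,
    save_feature_table,
    screen_omics,
    split_train_test,
)


def _write_csv(path, text):
    path.write_text(text)
    return path


class TestLoad:
    def test_dimensions_and_order_preserved(self, tmp_path):
        p = _write_csv(
            tmp_path / "t.csv",
            "Sample,B,A\nS3,1,2\nS1,3,4\nS2,5,6\n",
        )
        t = load_feature_table(p, "imaging")
        assert (t.n_samples, t.n_features) == (3, 2)
        assert t.sample_ids == ["S3", "S1", "S2"]
        assert t.feature_names == ["B", "A"]
        np.testing.assert_array_equal(t.values, [[1, 2], [3, 4], [5, 6]])

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", "Sample,A\nS1,1\nS1,2\n")
        with pytest.raises(ValidationError, match="S1"):
            load_feature_table(p, "imaging")

    def test_duplicate_feature_name_rejected(self):
        with pytest.raises(ValidationError, match="A"):
            FeatureTable(["S1", "S2"], ["A", "A"], np.ones((2, 2)), "imaging")

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", "Sample,A,B\nS1,1,x\n")
        with pytest.raises(ValidationError, match=r"'S1'.*'B'"):
            load_feature_table(p, "imaging")

    def test_missing_cell_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", "Sample,A,B\nS1,1,\nS2,2,3\n")
        with pytest.raises(ValidationError):
            load_feature_table(p, "imaging")

    def test_empty_table_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", "Sample\n")
        with pytest.raises(ValidationError):
            load_feature_table(p, "imaging")

    def test_case_study_shape_loads(self, tmp_path, rng):
        # 89 samples x 36 features, the shape of a published MRI feature set
        vals = rng.normal(size=(89, 36))
        t = FeatureTable(
            [f"P{i}" for i in range(89)],
            [f"F{j}" for j in range(36)],
            vals,
            "imaging",
        )
        p = tmp_path / "big.csv"
        save_feature_table(t, p)
        back = load_feature_table(p, "imaging")
        assert (back.n_samples, back.n_features) == (89, 36)
        np.testing.assert_allclose(back.values, vals, rtol=1e-9)


class TestMatchSamples:
    def test_intersection_oracle(self, rng):
        a = FeatureTable(["A", "B", "C"], ["F"], rng.normal(size=(3, 1)), "imaging")
        b = FeatureTable(["B", "C", "D"], ["G"], rng.normal(size=(3, 1)), "omics")
        ma, mb = match_samples(a, b)
        assert ma.sample_ids == mb.sample_ids == ["B", "C"]

    def test_reorder_only_when_same_ids(self, rng):
        vals = rng.normal(size=(3, 2))
        a = FeatureTable(["A", "B", "C"], ["F1", "F2"], vals, "imaging")
        b = FeatureTable(["C", "A", "B"], ["G"], rng.normal(size=(3, 1)), "omics")
        ma, mb = match_samples(a, b)
        assert ma.sample_ids == mb.sample_ids
        assert ma.n_samples == 3
        np.testing.assert_array_equal(ma.values, vals)  # a's order wins

    def test_idempotent(self, tiny_tables):
        a, b = tiny_tables
        once = match_samples(a, b)
        twice = match_samples(*once)
        for t1, t2 in zip(once, twice):
            assert t1.sample_ids == t2.sample_ids
            np.testing.assert_array_equal(t1.values, t2.values)

    def test_zero_common_samples(self, rng):
        a = FeatureTable(["A"], ["F"], [[1.0]], "imaging")
        b = FeatureTable(["B"], ["G"], [[1.0]], "omics")
        with pytest.raises(ValidationError, match="zero common"):
            match_samples(a, b)

    def test_case_sensitive(self):
        a = FeatureTable(["s1", "s2"], ["F"], [[1.0], [2.0]], "imaging")
        b = FeatureTable(["S1", "s2"], ["G"], [[1.0], [2.0]], "omics")
        ma, _ = match_samples(a, b)
        assert ma.sample_ids == ["s2"]


class TestScreenOmics:
    def test_count_oracle(self, rng):
        # 10 genes over 5 samples; genes 0-4 get >=3 values >= 5, genes 5-9 don't
        vals = rng.uniform(0, 4, size=(5, 10))
        vals[:3, :5] = 6.0
        t = FeatureTable(
            [f"S{i}" for i in range(5)], [f"G{j}" for j in range(10)], vals, "omics"
        )
        kept = screen_omics(t, min_value=5, min_samples=3)
        assert kept.feature_names == [f"G{j}" for j in range(5)]
        assert kept.sample_ids == t.sample_ids

    def test_all_zero_gene_dropped(self):
        t = FeatureTable(
            ["S1", "S2"], ["G0", "G1"], [[0.0, 6.0], [0.0, 6.0]], "omics"
        )
        kept = screen_omics(t, min_value=5, min_samples=1)
        assert kept.feature_names == ["G1"]

    def test_row_order_invariance(self, rng):
        vals = rng.uniform(0, 10, size=(6, 8))
        ids = [f"S{i}" for i in range(6)]
        t = FeatureTable(ids, [f"G{j}" for j in range(8)], vals, "omics")
        perm = [3, 0, 5, 1, 4, 2]
        t2 = t.select_samples([ids[i] for i in perm])
        assert (
            screen_omics(t, 5, 3).feature_names
            == screen_omics(t2, 5, 3).feature_names
        )

    def test_min_samples_exceeds_n(self, tiny_tables):
        _, omics = tiny_tables
        with pytest.raises(ConfigError):
            screen_omics(omics, 5, 30)

    def test_cohort_scale_screen_preset_accepted(self, rng):
        # the FPKM >= 5 in >= 30 patients rule on a cohort-sized table
        vals = rng.uniform(5, 10, size=(40, 6))
        t = FeatureTable(
            [f"S{i}" for i in range(40)], [f"G{j}" for j in range(6)], vals, "omics"
        )
        screen_omics(t, min_value=5, min_samples=30)  # must not raise


class TestSplit:
    def _pair(self, n, rng):
        x = FeatureTable(
            [f"S{i}" for i in range(n)], ["F"], rng.normal(size=(n, 1)), "imaging"
        )
        y = FeatureTable(
            list(x.sample_ids), ["G"], rng.normal(size=(n, 1)), "omics"
        )
        return x, y

    def test_partition(self, rng):
        x, y = self._pair(10, rng)
        (xt, yt), (xe, ye) = split_train_test(x, y, SplitSpec(0.8, 0.2, 1))
        assert len(xe.sample_ids) == 2 and len(xt.sample_ids) == 8
        assert set(xt.sample_ids) | set(xe.sample_ids) == set(x.sample_ids)
        assert not set(xt.sample_ids) & set(xe.sample_ids)
        assert xt.sample_ids == yt.sample_ids and xe.sample_ids == ye.sample_ids

    def test_default_sizes(self, rng):
        x, y = self._pair(100, rng)
        _, (xe, _) = split_train_test(x, y, SplitSpec(0.9, 0.1, 0))
        assert xe.n_samples == 10

    def test_deterministic(self, rng):
        x, y = self._pair(20, rng)
        s = SplitSpec(0.7, 0.3, 99)
        a = split_train_test(x, y, s)
        b = split_train_test(x, y, s)
        assert a[0][0].sample_ids == b[0][0].sample_ids
        assert a[1][0].sample_ids == b[1][0].sample_ids

    def test_bad_fractions(self):
        with pytest.raises(ConfigError):
            SplitSpec(0.9, 0.5, 0)
        with pytest.raises(ConfigError):
            SplitSpec(1.2, 0.1, 0)

    def test_empty_side_rejected(self, rng):
        x, y = self._pair(3, rng)
        with pytest.raises(ConfigError):
            split_train_test(x, y, SplitSpec(0.9, 0.1, 0))  # round(0.3) = 0 test


class TestScalers:
    @pytest.mark.parametrize("method", ["stand_scaler", "min_max", "max_abs"])
    def test_round_trip(self, method, rng):
        t = FeatureTable(
            [f"S{i}" for i in range(7)],
            ["A", "B"],
            rng.normal(size=(7, 2)) * 5 + 2,
            "imaging",
        )
        p = fit_scaler(t, method)
        back = invert_scaler(apply_scaler(t, p), p)
        np.testing.assert_allclose(back.values, t.values, atol=1e-9)

    def test_stand_scaler_moments(self, rng):
        t = FeatureTable(
            [f"S{i}" for i in range(9)], ["A"], rng.normal(size=(9, 1)), "imaging"
        )
        out = apply_scaler(t, fit_scaler(t, "stand_scaler"))
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std(ddof=0) - 1) < 1e-9

    def test_min_max_example(self):
        t = FeatureTable(["a", "b", "c"], ["F"], [[2.0], [4.0], [6.0]], "imaging")
        out = apply_scaler(t, fit_scaler(t, "min_max"))
        np.testing.assert_allclose(out.values.ravel(), [0, 0.5, 1])

    def test_max_abs_example(self):
        t = FeatureTable(["a", "b", "c"], ["F"], [[-2.0], [1.0], [4.0]], "imaging")
        out = apply_scaler(t, fit_scaler(t, "max_abs"))
        np.testing.assert_allclose(out.values.ravel(), [-0.5, 0.25, 1])

    def test_constant_feature_maps_to_zero_with_warning(self):
        t = FeatureTable(["a", "b"], ["C"], [[3.0], [3.0]], "imaging")
        with pytest.warns(UserWarning, match="constant"):
            p = fit_scaler(t, "stand_scaler")
        assert np.all(apply_scaler(t, p).values == 0)

    def test_feature_name_mismatch_rejected(self, rng):
        t = FeatureTable(["a", "b"], ["A"], rng.normal(size=(2, 1)), "imaging")
        u = FeatureTable(["a", "b"], ["B"], rng.normal(size=(2, 1)), "imaging")
        with pytest.raises(ValidationError):
            apply_scaler(u, fit_scaler(t, "min_max"))

    def test_unknown_method(self, tiny_tables):
        with pytest.raises(ConfigError):
            fit_scaler(tiny_tables[0], "zscore")
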