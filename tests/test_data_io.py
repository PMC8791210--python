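"""Feature-table reading, covariate adjustment, filtering, standardization."""

import numpy as np
import pytest

import sparsecca as sc
from sparsecca.data_io import TableError, zscore


class TestReadWrite:
    @pytest.mark.parametrize("suffix", [".csv", ".tsv"])
    def test_roundtrip_identity(self, tmp_path, table_factory, suffix):
        rng = np.random.default_rng(0)
        t = table_factory(rng.standard_normal((5, 3)),
                          group_labels=np.array(["a", "a", "b", "b", "a"],
                                                dtype=object))
        path = tmp_path / f"t{suffix}"
        sc.write_table(t, path, group_column="group")
        back = sc.read_feature_table(path, group_column="group")
        assert back.values.shape == (5, 3)
        assert np.abs(back.values - t.values).max() < 1e-12
        assert back.subject_ids == t.subject_ids
        assert back.variable_names == t.variable_names
        assert list(back.group_labels) == list(t.group_labels)

    def test_small_csv(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,a,b\ns1,1,2\ns2,3,4\ns3,5,6\n")
        t = sc.read_feature_table(path)
        assert t.values.shape == (3, 2)
        assert t.subject_ids == ["s1", "s2", "s3"]

    def test_blank_cell_names_the_cell(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,a,b\ns1,1,2\ns2,,4\n")
        with pytest.raises(TableError, match="s2.*'a'"):
            sc.read_feature_table(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,a,b\ns1,1,2\ns2,oops,4\n")
        with pytest.raises(TableError, match="oops"):
            sc.read_feature_table(path)

    def test_drop_missing_policy(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,a,b\ns1,1,2\ns2,,4\ns3,5,6\n")
        t = sc.read_feature_table(path, drop_missing_subjects=True)
        assert t.subject_ids == ["s1", "s3"]

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,a\ns1,1\ns1,2\n")
        with pytest.raises(TableError, match="duplicate subject"):
            sc.read_feature_table(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sc.read_feature_table(tmp_path / "nope.csv")


class TestCovariateAdjust:
    def test_perfectly_explained_column_zeroed(self, table_factory):
        cov = np.arange(8.0)
        t = table_factory(np.column_stack([2 * cov + 5, np.ones(8) + cov ** 2]))
        out = sc.covariate_adjust(t, cov, columns=["v1"])
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_unselected_columns_bit_identical(self, table_factory):
        rng = np.random.default_rng(1)
        t = table_factory(rng.standard_normal((10, 3)))
        out = sc.covariate_adjust(t, rng.standard_normal(10), columns=["v2"])
        assert np.array_equal(out.values[:, [0, 2]], t.values[:, [0, 2]])

    def test_orthogonal_covariate_leaves_centered_column(self, table_factory):
        # covariate orthogonal to a centered column -> slope 0, only the
        # intercept (mean) is removed
        col = np.array([1.0, -1.0, 2.0, -2.0])
        cov = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(col @ cov) < 1e-12
        t = table_factory(col[:, None])
        out = sc.covariate_adjust(t, cov)
        assert np.abs(out.values[:, 0] - col).max() < 1e-12

    def test_residuals_uncorrelated_with_covariate(self, table_factory):
        rng = np.random.default_rng(2)
        col = rng.standard_normal(20)
        cov = rng.standard_normal(20)
        out = sc.covariate_adjust(table_factory(col[:, None]), cov)
        r = np.corrcoef(out.values[:, 0], cov)[0, 1]
        assert abs(r) < 1e-10

    def test_constant_covariate_rejected(self, table_factory):
        t = table_factory(np.random.default_rng(3).standard_normal((5, 2)))
        with pytest.raises(TableError, match="constant"):
            sc.covariate_adjust(t, np.ones(5))


class TestFilterVariables:
    def test_identical_columns_second_removed(self, table_factory):
        col = np.arange(6.0)
        t = table_factory(np.column_stack([col, col]))
        out, log = sc.filter_variables(t)
        assert out.variable_names == ["v1"]
        assert log[0].variable == "v2" and log[0].partner == "v1"
        assert log[0].reason == "high_corr"

    def test_moderate_correlation_retained(self, table_factory):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(200)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(200)
        out, log = sc.filter_variables(table_factory(np.column_stack([a, b])))
        assert out.n_variables == 2 and not log

    def test_low_sd_removed_first(self, table_factory):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((30, 3))
        vals[:, 1] *= 1e-6
        out, log = sc.filter_variables(table_factory(vals), min_sd=1e-3)
        assert out.variable_names == ["v1", "v3"]
        assert log[0].reason == "low_sd"

    def test_greedy_scan_matches_bruteforce_oracle(self, table_factory):
        # 10 columns with a 3-column near-duplicate block
        rng = np.random.default_rng(6)
        base = rng.standard_normal((40, 7))
        dup = base[:, 2:3] + 1e-3 * rng.standard_normal((40, 3))
        vals = np.column_stack([base[:, :3], dup, base[:, 3:]])
        t = table_factory(vals)
        out, log = sc.filter_variables(t, corr_threshold=0.85)

        # independent brute-force re-application of the greedy rule
        C = np.corrcoef(vals, rowvar=False)
        alive = list(range(10))
        for a in range(10):
            if a not in alive:
                continue
            for b in range(a + 1, 10):
                if b in alive and abs(C[a, b]) > 0.85:
                    alive.remove(b)
        expected = [t.variable_names[i] for i in alive]
        assert out.variable_names == expected

    def test_row_order_invariance_and_log_determinism(self, table_factory):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((25, 6))
        vals[:, 3] = vals[:, 0] + 1e-4 * rng.standard_normal(25)
        t = table_factory(vals)
        out1, log1 = sc.filter_variables(t)
        shuffled = t.take_subjects(rng.permutation(25))
        out2, log2 = sc.filter_variables(shuffled)
        assert out1.variable_names == out2.variable_names
        # the log alone determines the survivor set
        removed = {r.variable for r in log1}
        assert out1.variable_names == [v for v in t.variable_names
                                       if v not in removed]

    def test_all_removed_is_error(self, table_factory):
        t = table_factory(np.ones((5, 2)))
        with pytest.raises(TableError):
            sc.filter_variables(t, min_sd=1.0)


class TestStandardizePair:
    def test_unit_example(self, table_factory):
        tx = table_factory(np.array([[1.0, 5], [2, 7], [3, 9]]))
        ty = table_factory(np.array([[4.0], [5], [6]]))
        pair = sc.standardize_pair(tx, ty)
        assert np.abs(pair.X[:, 0] - [-1, 0, 1]).max() < 1e-12
        assert np.abs(pair.Y[:, 0] - [-1, 0, 1]).max() < 1e-12

    def test_columns_standardized(self, table_factory):
        rng = np.random.default_rng(8)
        pair = sc.standardize_pair(table_factory(rng.standard_normal((12, 4))),
                                   table_factory(rng.standard_normal((12, 5))))
        for M in (pair.X, pair.Y):
            assert np.abs(M.mean(axis=0)).max() < 1e-10
            assert np.abs(M.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_idempotent(self, table_factory):
        rng = np.random.default_rng(9)
        t1 = table_factory(rng.standard_normal((15, 3)))
        t2 = table_factory(rng.standard_normal((15, 4)))
        p1 = sc.standardize_pair(t1, t2)
        p2 = sc.standardize_pair(
            sc.FeatureTable(p1.subject_ids, p1.names_x, p1.X),
            sc.FeatureTable(p1.subject_ids, p1.names_y, p1.Y))
        assert np.abs(p1.X - p2.X).max() < 1e-12
        assert np.abs(p1.Y - p2.Y).max() < 1e-12

    def test_row_alignment_by_subject_id(self, table_factory):
        rng = np.random.default_rng(10)
        tx = table_factory(rng.standard_normal((8, 2)))
        ty = table_factory(rng.standard_normal((8, 3)))
        aligned = sc.standardize_pair(tx, ty)
        perm = rng.permutation(8)
        shuffled = sc.standardize_pair(tx, ty.take_subjects(perm))
        assert np.abs(aligned.Y - shuffled.Y).max() < 1e-12

    def test_subject_mismatch_rejected(self, table_factory):
        tx = table_factory(np.eye(3), ids=["a", "b", "c"])
        ty = table_factory(np.eye(3), ids=["a", "b", "d"])
        with pytest.raises(TableError, match="subject sets differ"):
            sc.standardize_pair(tx, ty)

    def test_zero_variance_column_named(self, table_factory):
        tx = table_factory(np.column_stack([np.arange(4.0), np.ones(4)]))
        ty = table_factory(np.random.default_rng(1).standard_normal((4, 2)))
        with pytest.raises(TableError, match="v2"):
            sc.standardize_pair(tx, ty)


def test_zscore_matches_pandas_convention():
    rng = np.random.default_rng(11)
    M = rng.standard_normal((9, 3)) * 4 + 2
    Z = zscore(M)
    assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-12
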