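"""QC filters: exact boundary semantics, brute-force recounts, invariances."""

import numpy as np
import pandas as pd
import pytest

from oasubtypes import io as oio
from oasubtypes.io import ValidationError
from oasubtypes.qc import (cpm, filter_genes_control_variance,
                           filter_genes_min_expression,
                           filter_samples_by_depth, log2cpm, select_hvg)
from oasubtypes.simulate import CohortConfig, generate_cohort


def _frame(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestReadCountMatrix:
    def test_tsv_round_trip_preserves_dimnames(self, tmp_path):
        df = _frame([[1, 2], [3, 4], [5, 6]], genes=["a", "b", "c"])
        oio.write_count_matrix(df, tmp_path / "m.tsv")
        back = oio.read_count_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back, df)

    def test_duplicate_gene_id_error_names_it(self, tmp_path):
        (tmp_path / "dup.tsv").write_text(
            "\ts1\ts2\ngeneA\t1\t2\ngeneA\t3\t4\n")
        with pytest.raises(ValidationError, match="geneA"):
            oio.read_count_matrix(tmp_path / "dup.tsv")

    def test_negative_entry_rejected(self, tmp_path):
        (tmp_path / "neg.tsv").write_text("\ts1\ngeneA\t-3\n")
        with pytest.raises(ValidationError, match="geneA"):
            oio.read_count_matrix(tmp_path / "neg.tsv")

    def test_mtx_equals_tsv(self, tmp_path, rng):
        df = _frame(rng.integers(0, 50, size=(6, 4)))
        oio.write_count_matrix(df, tmp_path / "m.tsv")
        oio.write_count_matrix(df, tmp_path / "m.mtx", format="mtx")
        pd.testing.assert_frame_equal(
            oio.read_count_matrix(tmp_path / "m.mtx", format="mtx"),
            oio.read_count_matrix(tmp_path / "m.tsv"))


class TestDepthFilter:
    def test_window_bounds_inclusive(self):
        totals = [400_000, 500_000, 2_000_000, 2_000_001]
        df = _frame([totals])  # one gene carrying the full column total
        kept = filter_samples_by_depth(df)
        assert list(kept.columns) == ["s1", "s2"]

    def test_identity_when_all_inside(self):
        df = _frame([[600_000, 1_000_000]])
        pd.testing.assert_frame_equal(filter_samples_by_depth(df), df)

    def test_matches_brute_force_on_synthetic_cohort(self):
        cfg = CohortConfig(n_patients=200, n_genes=300,
                           library_size_range=(400_000, 2_100_000),
                           n_lr_pairs=60, n_planted_crosstalk_per_subtype=5,
                           seed=7)
        counts, _, _ = generate_cohort(cfg)
        df = counts["cartilage"]
        kept = filter_samples_by_depth(df)
        expected = [s for s in df.columns
                    if 500_000 <= df[s].sum() <= 2_000_000]
        assert list(kept.columns) == expected
        assert 0 < len(expected) < df.shape[1]  # the wide range exercises both tails

    def test_all_removed_is_an_error(self):
        df = _frame([[10, 20]])
        with pytest.raises(ValidationError, match="every sample"):
            filter_samples_by_depth(df)


class TestCPM:
    def test_arithmetic(self):
        df = _frame([[1], [3]])
        out = cpm(df)
        assert out.iloc[:, 0].tolist() == [250_000.0, 750_000.0]

    def test_column_sums_are_one_million(self, rng):
        df = _frame(rng.integers(1, 100, size=(20, 5)))
        assert np.allclose(cpm(df).sum(axis=0), 1e6, rtol=1e-6)

    def test_scale_invariance(self, rng):
        df = _frame(rng.integers(1, 100, size=(10, 3)))
        scaled = df.copy()
        scaled["s1"] *= 10
        pd.testing.assert_frame_equal(cpm(df), cpm(scaled))

    def test_zero_depth_sample_error_names_it(self):
        df = _frame([[5, 0]])
        with pytest.raises(ValidationError, match="s1"):
            cpm(df)


class TestControlVarianceFilter:
    def test_constant_gene_retained(self):
        expr = _frame([[8.0, 8.0, 100.0]], samples=["c1", "c2", "oa1"])
        out = filter_genes_control_variance(expr, ["c1", "c2"])
        assert list(out.index) == ["g0"]

    def test_variance_eight_removed(self):
        # log2(CPM+1) of (0, 15) is (0, 4): sample variance 8 > 3
        expr = _frame([[0.0, 15.0], [10.0, 10.0]], samples=["c1", "c2"])
        out = filter_genes_control_variance(expr, ["c1", "c2"])
        assert list(out.index) == ["g1"]

    def test_matches_brute_force(self, rng):
        expr = _frame(rng.uniform(0, 200, size=(60, 8)))
        controls = ["s0", "s1", "s2"]
        out = filter_genes_control_variance(expr, controls, max_variance=1.5)
        logx = np.log2(expr[controls] + 1)
        expected = [g for g in expr.index
                    if np.var(logx.loc[g], ddof=1) <= 1.5]
        assert list(out.index) == expected

    def test_fewer_than_two_controls_rejected(self):
        expr = _frame([[1.0, 2.0]])
        with pytest.raises(ValidationError, match="2 control"):
            filter_genes_control_variance(expr, ["s0"])


class TestMinExpressionFilter:
    def test_cpm_exactly_five_removed(self):
        expr = _frame([[5.0] * 20])
        out = filter_genes_min_expression(expr, expr.columns)
        assert out.empty

    def test_cpm_six_in_fifteen_samples_kept(self):
        row = [6.0] * 15 + [0.0] * 5
        expr = _frame([row])
        out = filter_genes_min_expression(expr, expr.columns)
        assert list(out.index) == ["g0"]

    def test_matches_brute_force(self, rng):
        expr = _frame(rng.uniform(0, 12, size=(80, 30)))
        oa = list(expr.columns[:25])
        out = filter_genes_min_expression(expr, oa, min_cpm=5, min_samples=10)
        expected = [g for g in expr.index
                    if sum(expr.loc[g, s] > 5 for s in oa) >= 10]
        assert list(out.index) == expected


class TestSelectHVG:
    def test_n_equal_gene_count_is_identity(self, rng):
        expr = _frame(rng.uniform(0, 100, size=(12, 6)))
        pd.testing.assert_frame_equal(select_hvg(expr, 12), expr)

    def test_varying_gene_beats_constant(self):
        expr = _frame([[5.0, 5.0, 5.0], [0.0, 50.0, 400.0]])
        assert list(select_hvg(expr, 1).index) == ["g1"]

    def test_matches_brute_force_sort(self, rng):
        expr = _frame(rng.uniform(0, 300, size=(200, 10)))
        out = select_hvg(expr, 50)
        sd = np.log2(expr + 1).std(axis=1, ddof=1)
        expected = set(sorted(expr.index, key=lambda g: (-sd[g], g))[:50])
        assert set(out.index) == expected

    def test_n_too_large_rejected(self, rng):
        expr = _frame(rng.uniform(0, 10, size=(5, 3)))
        with pytest.raises(ValidationError):
            select_hvg(expr, 6)


class TestFilterProperties:
    def test_filters_commute_with_permutation(self, rng):
        expr = _frame(rng.uniform(0, 12, size=(40, 20)))
        perm_g = rng.permutation(expr.index)
        perm_s = rng.permutation(expr.columns)
        permuted = expr.loc[perm_g, perm_s]
        out = filter_genes_min_expression(expr, expr.columns, 5, 8)
        out_p = filter_genes_min_expression(permuted, permuted.columns, 5, 8)
        assert set(out.index) == set(out_p.index)

    def test_filters_idempotent(self, rng):
        expr = _frame(rng.uniform(0, 12, size=(40, 20)))
        once = filter_genes_min_expression(expr, expr.columns, 5, 8)
        twice = filter_genes_min_expression(once, once.columns, 5, 8)
        pd.testing.assert_frame_equal(once, twice)
        counts = _frame(rng.integers(400_000, 2_500_000, size=(1, 12)))
        once = filter_samples_by_depth(counts)
        pd.testing.assert_frame_equal(filter_samples_by_depth(once), once)

    def test_cpm_not_renormalized_after_gene_filter(self, rng):
        counts = _frame(rng.integers(0, 80, size=(30, 4)))
        expr = cpm(counts)
        filtered = filter_genes_min_expression(expr, expr.columns, 40_000, 2)
        assert filtered.shape[0] < expr.shape[0]
        # column sums drop below 1e6: the single normalization is preserved
        assert (filtered.sum(axis=0) < 1e6 - 1).all()
        pd.testing.assert_frame_equal(filtered, expr.loc[filtered.index])
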