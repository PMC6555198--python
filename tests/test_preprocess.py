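import numpy as np
import pytest

from transtat.exceptions import ValidationError
from transtat.io_formats import ControlGeneSet, GeneLengthTable
from transtat.preprocess import (
    FilterSpec,
    filter_low_expression,
    normalize_fpkm,
    normalize_rpkm,
    normalize_ruv,
    normalize_tpm,
    normalize_upper_quartile,
    rle_profile,
)

from conftest import make_matrix


class TestFilter:
    def test_all_below_removed(self):
        m = make_matrix([[0, 0, 0], [10, 10, 10]])
        res = filter_low_expression(m, FilterSpec(min_value=5, min_samples=2))
        assert res.matrix.gene_ids == ["g1"]
        assert res.n_removed == 1
        assert res.removed_genes == ["g0"]

    def test_threshold_is_strict(self):
        # (6,4,4): only one sample strictly exceeds 5
        m = make_matrix([[6, 4, 4], [9, 9, 9]])
        res2 = filter_low_expression(m, FilterSpec(5, 2))
        assert "g0" not in res2.matrix.gene_ids
        res1 = filter_low_expression(m, FilterSpec(5, 1))
        assert "g0" in res1.matrix.gene_ids

    def test_boundary_value_not_exceeding(self):
        m = make_matrix([[5, 5, 5], [9, 9, 9]])
        res = filter_low_expression(m, FilterSpec(5, 1))
        assert res.matrix.gene_ids == ["g1"]

    def test_all_removed_error(self):
        m = make_matrix([[1, 1], [2, 2]])
        with pytest.raises(ValidationError, match="all genes"):
            filter_low_expression(m, FilterSpec(100, 1))

    def test_min_samples_exceeds_samples(self):
        m = make_matrix([[1, 1]])
        with pytest.raises(ValidationError, match="min_samples"):
            filter_low_expression(m, FilterSpec(0, 3))

    def test_idempotent(self, random_counts):
        spec = FilterSpec(50, 2)
        once = filter_low_expression(random_counts, spec).matrix
        twice = filter_low_expression(once, spec).matrix
        assert once.gene_ids == twice.gene_ids
        np.testing.assert_array_equal(once.values, twice.values)


class TestFpkmTpm:
    def test_fpkm_hand_value(self):
        # count=100, length=1000 bp, column total 1e6 -> 100.0
        m = make_matrix([[100], [999900]], gene_ids=["a", "b"], sample_ids=["s"])
        lengths = GeneLengthTable(lengths={"a": 1000, "b": 2000})
        out = normalize_fpkm(m, lengths)
        assert out.values[0, 0] == pytest.approx(100.0)
        assert out.is_raw_counts is False

    def test_rpkm_is_fpkm(self):
        assert normalize_rpkm is normalize_fpkm

    def test_zero_count_stays_zero(self):
        m = make_matrix([[0], [10]], gene_ids=["a", "b"], sample_ids=["s"])
        lengths = GeneLengthTable(lengths={"a": 12345, "b": 100})
        assert normalize_fpkm(m, lengths).values[0, 0] == 0.0

    def test_fpkm_column_scale_invariance(self, random_counts):
        lengths = GeneLengthTable(
            lengths={g: 100 * (i + 1) for i, g in enumerate(random_counts.gene_ids)}
        )
        doubled = make_matrix(
            random_counts.values * 2,
            gene_ids=random_counts.gene_ids,
            sample_ids=random_counts.sample_ids,
        )
        np.testing.assert_allclose(
            normalize_fpkm(random_counts, lengths).values,
            normalize_fpkm(doubled, lengths).values,
            rtol=1e-12,
        )

    def test_fpkm_missing_length_error(self):
        m = make_matrix([[1]], gene_ids=["a"], sample_ids=["s"])
        with pytest.raises(ValidationError, match="a"):
            normalize_fpkm(m, GeneLengthTable(lengths={"b": 100}))

    def test_fpkm_requires_raw(self, small_matrix):
        m = make_matrix(small_matrix.values, is_raw_counts=False)
        with pytest.raises(ValidationError, match="raw"):
            normalize_fpkm(m, GeneLengthTable(lengths={g: 100 for g in m.gene_ids}))

    def test_tpm_hand_value(self):
        # rates (0.01, 0.02) -> shares 1/3 and 2/3 of 1e6
        m = make_matrix([[10], [40]], gene_ids=["a", "b"], sample_ids=["s"])
        lengths = GeneLengthTable(lengths={"a": 1000, "b": 2000})
        out = normalize_tpm(m, lengths)
        np.testing.assert_allclose(out.values[:, 0], [1e6 / 3, 2e6 / 3])

    def test_tpm_single_gene_exact(self):
        m = make_matrix([[123]], gene_ids=["a"], sample_ids=["s"])
        out = normalize_tpm(m, GeneLengthTable(lengths={"a": 777}))
        assert out.values[0, 0] == pytest.approx(1e6)

    def test_tpm_columns_sum_to_million(self, random_counts):
        m = make_matrix(random_counts.values + 1)  # avoid all-zero columns
        lengths = GeneLengthTable(lengths={g: 500 + 7 * i for i, g in enumerate(m.gene_ids)})
        out = normalize_tpm(m, lengths)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_tpm_equals_rescaled_fpkm(self, random_counts):
        m = make_matrix(random_counts.values + 1)
        lengths = GeneLengthTable(lengths={g: 500 + 7 * i for i, g in enumerate(m.gene_ids)})
        fpkm = normalize_fpkm(m, lengths).values
        tpm = normalize_tpm(m, lengths).values
        rescaled = 1e6 * fpkm / fpkm.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(tpm, rescaled, rtol=1e-9)

    def test_tpm_zero_column_error(self):
        m = make_matrix([[0, 1]], gene_ids=["a"], sample_ids=["s1", "s2"])
        with pytest.raises(ValidationError, match="s1"):
            normalize_tpm(m, GeneLengthTable(lengths={"a": 100}))


class TestUpperQuartile:
    def test_identical_columns_ratio_one(self):
        col = np.array([1, 5, 10, 50, 100], dtype=float)
        m = make_matrix(np.column_stack([col, col]))
        out = normalize_upper_quartile(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_doubled_column_equalized(self):
        col = np.array([1, 5, 10, 50, 100], dtype=float)
        m = make_matrix(np.column_stack([col, 2 * col]))
        out = normalize_upper_quartile(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], rtol=1e-12)

    def test_all_zero_gene_excluded_from_quartile(self):
        col = np.array([1, 5, 10, 50, 100], dtype=float)
        base = make_matrix(np.column_stack([col, 2 * col]))
        with_zero = make_matrix(
            np.vstack([np.column_stack([col, 2 * col]), [0, 0]]),
            gene_ids=[f"g{i}" for i in range(5)] + ["zz"],
        )
        out_base = normalize_upper_quartile(base)
        out_zero = normalize_upper_quartile(with_zero)
        np.testing.assert_allclose(out_zero.values[:5], out_base.values)
        np.testing.assert_array_equal(out_zero.values[5], [0, 0])

    def test_equalizes_75th_percentile(self, random_counts):
        m = make_matrix(random_counts.values + 1)
        out = normalize_upper_quartile(m)
        q = np.percentile(out.values, 75, axis=0)
        np.testing.assert_allclose(q, q[0], rtol=1e-12)

    def test_zero_quartile_error(self):
        vals = np.zeros((4, 2))
        vals[0, 0] = 5  # sample 2 quartile stays 0
        m = make_matrix(vals)
        with pytest.raises(ValidationError, match="75th"):
            normalize_upper_quartile(m)


class TestRuv:
    def test_constant_controls_no_change(self, rng):
        base = rng.integers(10, 1000, size=(30, 4)).astype(float)
        base[:5] = base[:5, :1]  # controls constant across samples
        m = make_matrix(base)
        controls = ControlGeneSet(genes=set(m.gene_ids[:5]))
        out = normalize_ruv(m, controls, k=1)
        rel = np.abs(out.values - m.values) / np.maximum(m.values, 1)
        assert rel.max() < 1e-6

    def test_planted_factor_removed(self, rng):
        # noise-free: each gene constant across samples apart from the factor
        base = np.tile(rng.lognormal(4, 1, 40)[:, None], (1, 5))
        factors = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        m = make_matrix(np.round(base * factors[None, :]) + 1)
        controls = ControlGeneSet(genes=set(m.gene_ids[:8]))
        out = normalize_ruv(m, controls, k=1)

        def ctrl_logvar(mat):
            logs = np.log(mat.values[:8] + 1)
            return np.var(logs, axis=1).mean()

        assert ctrl_logvar(out) < 0.1 * ctrl_logvar(m)

    def test_k_too_large_error(self, small_matrix):
        controls = ControlGeneSet(genes={"a", "b", "c"})
        with pytest.raises(ValidationError, match="k"):
            normalize_ruv(small_matrix, controls, k=3)

    def test_fewer_controls_than_k_error(self):
        m = make_matrix(np.ones((5, 4)) * 7)
        with pytest.raises(ValidationError, match="control"):
            normalize_ruv(m, ControlGeneSet(genes={"g0"}), k=2)

    def test_residual_orthogonal_to_factors(self, rng):
        base = rng.lognormal(3, 0.8, size=(30, 6))
        factors = np.exp(rng.normal(0, 0.5, 6))
        m = make_matrix(np.round(base * factors[None, :]) + 1)
        controls = ControlGeneSet(genes=set(m.gene_ids[:6]))
        out = normalize_ruv(m, controls, k=1, pseudocount=1.0)
        # recompute the factor direction from the input controls
        log_ctrl = np.log(m.values[:6] + 1)
        cc = log_ctrl - log_ctrl.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(cc, full_matrices=False)
        w = vt[0]
        resid = np.log(out.values[:6] + 1)
        resid = resid - resid.mean(axis=1, keepdims=True)
        assert np.abs(resid @ w).max() < 1e-6


class TestRle:
    def test_identical_samples_all_zero(self):
        col = np.array([3, 9, 27], dtype=float)
        m = make_matrix(np.column_stack([col, col, col]))
        prof = rle_profile(m)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_two_sample_symmetry_about_zero(self):
        col = np.array([10, 100, 1000], dtype=float)
        m = make_matrix(np.column_stack([col, 2 * col + 1]))  # +1 keeps log(2) exact after pseudocount
        prof = rle_profile(m, pseudocount=1.0)
        np.testing.assert_allclose(prof.values[:, 0], -prof.values[:, 1], atol=1e-12)
        np.testing.assert_allclose(
            prof.values[:, 1] - prof.values[:, 0], np.log(2), atol=1e-12
        )

    def test_gene_median_zero_odd_samples(self, rng):
        m = make_matrix(rng.integers(0, 100, size=(20, 5)).astype(float))
        prof = rle_profile(m)
        np.testing.assert_allclose(np.median(prof.values, axis=1), 0.0, atol=1e-12)

    def test_single_sample_error(self):
        m = make_matrix([[1], [2]])
        with pytest.raises(ValidationError, match="2 samples"):
            rle_profile(m)

    def test_summary_shape(self, random_counts):
        prof = rle_profile(random_counts)
        assert list(prof.summary["sample"]) == random_counts.sample_ids
        assert {"min", "q25", "median", "q75", "max"} <= set(prof.summary.columns)
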