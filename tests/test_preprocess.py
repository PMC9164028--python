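"""Normalization arithmetic against hand-derived values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexnet import (
    CoexnetError,
    ExpressionMatrix,
    filter_genes,
    log_transform,
    normalize_housekeeping,
    normalize_median,
    normalize_median_of_ratios,
    normalize_quantile,
    normalize_tmm,
)
from coexnet.preprocess import _tmm_factor, tmm_factors


def em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestMedian:
    def test_hand_example(self):
        # medians 2 and 4, mean 3 -> factors 3/2 and 3/4
        m = em(np.array([[1, 2], [2, 4], [3, 6]]))
        out = normalize_median(m)
        assert np.allclose(out.values.T, [[1.5, 3, 4.5], [1.5, 3, 4.5]])

    def test_single_sample_unchanged(self):
        m = em([[1], [2], [3]])
        assert np.array_equal(normalize_median(m).values, m.values)

    def test_identical_samples_unchanged(self):
        m = em([[1, 1], [5, 5], [2, 2]])
        assert np.array_equal(normalize_median(m).values, m.values)

    def test_equalizes_all_sample_medians(self):
        rng = np.random.default_rng(3)
        m = em(rng.uniform(1, 50, size=(11, 6)))
        out = normalize_median(m)
        meds = np.median(out.values, axis=0)
        assert np.allclose(meds, meds[0])

    def test_zero_median_names_sample(self):
        m = em([[0, 1], [0, 2], [1, 3]], samples=["bad", "ok"])
        with pytest.raises(CoexnetError, match="bad"):
            normalize_median(m)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = em(rng.uniform(1, 10, size=(9, 5)))
        once = normalize_median(m)
        twice = normalize_median(once)
        assert np.allclose(twice.values, once.values, atol=1e-12)


class TestQuantile:
    def test_hand_example(self):
        # rank means: (1+2)/2=1.5, (3+4)/2=3.5, (5+6)/2=5.5
        m = em(np.array([[5, 4], [2, 1], [3, 6]]))
        out = normalize_quantile(m)
        assert np.allclose(out.values.T, [[5.5, 1.5, 3.5], [3.5, 1.5, 5.5]])

    def test_identical_samples_unchanged(self):
        m = em([[3, 3], [1, 1], [2, 2]])
        assert np.allclose(normalize_quantile(m).values, m.values)

    def test_sorted_columns_identical_exactly(self):
        rng = np.random.default_rng(5)
        m = em(rng.uniform(0, 9, size=(20, 4)))
        out = normalize_quantile(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 4):
            assert np.array_equal(np.sort(out.values[:, j]), ref)

    def test_ties_get_mean_of_spanned_rank_means(self):
        # sample 0 has a three-way tie spanning sort positions 1-3
        m = em(np.array([[0, 1], [2, 2], [2, 3], [2, 4], [9, 5]]))
        out = normalize_quantile(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        expected_tie = ref[1:4].mean()
        assert np.allclose(out.values[1:4, 0], expected_tie)
        assert out.values[0, 0] == ref[0] and out.values[4, 0] == ref[4]

    def test_single_sample_rejected(self):
        with pytest.raises(CoexnetError, match=">= 2 samples"):
            normalize_quantile(em([[1], [2]]))


class TestMedianOfRatios:
    def test_hand_example(self):
        m = em(np.array([[2, 4], [8, 16]]))
        out, factors = normalize_median_of_ratios(m)
        assert np.allclose(factors, [1 / math.sqrt(2), math.sqrt(2)])
        assert np.allclose(out.values[:, 0], [2 * math.sqrt(2), 8 * math.sqrt(2)])
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_identical_samples_give_unit_factors(self):
        m = em([[3, 3, 3], [7, 7, 7]])
        _, factors = normalize_median_of_ratios(m)
        assert np.allclose(factors, 1.0)

    def test_scale_equivariance_up_to_global_constant(self):
        # size factors are defined up to one global constant, so scaling a
        # sample by c must scale its factor by c *relative to the others*
        # and leave the normalized matrix proportional to the original
        rng = np.random.default_rng(6)
        base = rng.uniform(1, 20, size=(15, 4))
        scaled = base.copy()
        scaled[:, 2] *= 3.7
        ref, f0 = normalize_median_of_ratios(em(base))
        out, f1 = normalize_median_of_ratios(em(scaled))
        assert np.allclose((f1[2] / f1[0]), (f0[2] / f0[0]) * 3.7)
        ratio = out.values / ref.values
        assert np.allclose(ratio, ratio[0, 0])

    def test_zero_genes_excluded_from_reference(self):
        # g0 has a zero: the factor must come from g1/g2 only
        m = em(np.array([[0, 10], [4, 4], [9, 9]]))
        _, factors = normalize_median_of_ratios(m)
        assert np.allclose(factors, 1.0)

    def test_no_all_positive_gene_is_error(self):
        with pytest.raises(CoexnetError, match="positive"):
            normalize_median_of_ratios(em([[0, 1], [1, 0]]))

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        m = em(rng.uniform(1, 30, size=(12, 5)))
        once, _ = normalize_median_of_ratios(m)
        twice, f = normalize_median_of_ratios(once)
        assert np.allclose(f, 1.0, atol=1e-12)
        assert np.allclose(twice.values, once.values, atol=1e-12)


def naive_tmm_factor(obs, ref, lib_obs, lib_ref):
    """Independent loop-based trimmed weighted mean (naive ranks)."""
    rows = [
        (math.log2((o / lib_obs) / (r / lib_ref)),
         0.5 * math.log2((o / lib_obs) * (r / lib_ref)),
         (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
        for o, r in zip(obs, ref) if o > 0 and r > 0
    ]
    n = len(rows)

    def average_ranks(xs):
        order = sorted(range(n), key=lambda i: xs[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and xs[order[j + 1]] == xs[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rM = average_ranks([r[0] for r in rows])
    rA = average_ranks([r[1] for r in rows])
    loM = math.floor(n * 0.3) + 1
    hiM = n + 1 - loM
    loA = math.floor(n * 0.05) + 1
    hiA = n + 1 - loA
    keep = [
        i for i in range(n)
        if loM <= rM[i] <= hiM and loA <= rA[i] <= hiA
    ]
    num = sum(rows[i][0] / rows[i][2] for i in keep)
    den = sum(1 / rows[i][2] for i in keep)
    return 2 ** (num / den), keep


class TestTMM:
    def test_identical_samples_unit_factors(self):
        m = em([[10, 10], [20, 20], [5, 5]])
        _, factors = normalize_tmm(m)
        assert np.allclose(factors, 1.0)

    def test_pure_library_size_shift_removed(self):
        rng = np.random.default_rng(8)
        a = rng.integers(5, 500, size=30).astype(float)
        m = em(np.column_stack([a, 2 * a]))
        out, factors = normalize_tmm(m)
        assert np.allclose(factors, 1.0, atol=1e-9)
        assert np.allclose(out.values.sum(axis=0)[0], out.values.sum(axis=0)[1],
                           atol=1e-9)

    def test_factor_matches_naive_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            X = rng.integers(1, 1000, size=(40, 2)).astype(float)
            lib = X.sum(axis=0)
            expected, _keep = naive_tmm_factor(X[:, 1], X[:, 0], lib[1], lib[0])
            got = _tmm_factor(X[:, 1], X[:, 0], lib[1], lib[0])
            assert got == pytest.approx(expected, abs=1e-9)

    def test_extreme_gene_trimmed_out(self):
        # B doubles A except one wildly overexpressed gene; the trim must
        # exclude it, leaving only the constant log-ratio of the shift.
        rng = np.random.default_rng(10)
        a = rng.integers(50, 150, size=21).astype(float)
        b = 2 * a
        b[10] = a[10] * 50
        lib_a, lib_b = a.sum(), b.sum()
        expected, keep = naive_tmm_factor(b, a, lib_b, lib_a)
        assert 10 not in keep  # enumerated trim set drops the extreme gene
        got = _tmm_factor(b, a, lib_b, lib_a)
        assert got == pytest.approx(expected, abs=1e-9)
        # all retained M-values equal the pure shift ratio
        m_const = math.log2((2 / lib_b) / (1 / lib_a))
        assert got == pytest.approx(2 ** m_const, abs=1e-9)

    def test_factors_recentred_to_log_mean_zero(self):
        rng = np.random.default_rng(11)
        m = em(rng.integers(1, 400, size=(25, 4)).astype(float))
        factors = tmm_factors(m)
        assert np.log(factors).mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(CoexnetError, match=">= 2 samples"):
            normalize_tmm(em([[1], [2]]))

    def test_disjoint_support_rejected(self):
        with pytest.raises(CoexnetError, match="no positive gene"):
            _tmm_factor(np.array([0.0, 5.0]), np.array([5.0, 0.0]), 5.0, 5.0)


class TestHousekeeping:
    def test_hand_example(self):
        # HK medians 3 and 6, mean 4.5 -> factors 1.5 and 0.75
        m = em(np.array([[2, 4], [4, 8], [100, 1]]),
               genes=["hk1", "hk2", "other"])
        out = normalize_housekeeping(m, ["hk1", "hk2"])
        assert np.allclose(out.values[:, 0], [3, 6, 150])
        assert np.allclose(out.values[:, 1], [3, 6, 0.75])

    def test_equal_hk_medians_unchanged(self):
        m = em([[5, 5], [1, 9]], genes=["hk", "other"])
        out = normalize_housekeeping(m, ["hk"])
        assert np.array_equal(out.values, m.values)

    def test_single_hk_gene_divides_by_its_value(self):
        m = em(np.array([[2.0, 8.0], [3.0, 5.0]]), genes=["hk", "x"])
        out = normalize_housekeeping(m, ["hk"])
        # each sample scaled by mean(2,8)/hk_j
        assert np.allclose(out.values[0], [5.0, 5.0])

    def test_missing_hk_genes_listed(self):
        m = em([[1, 2]], genes=["g1"])
        with pytest.raises(CoexnetError, match="hkX"):
            normalize_housekeeping(m, ["hkX"])

    def test_unknown_hk_subset_ok(self):
        m = em([[2, 4], [1, 1]], genes=["hk1", "g"])
        out = normalize_housekeeping(m, ["hk1", "hk_missing"])
        assert np.allclose(np.median(out.values[[0]], axis=0), 3.0)


class TestFilter:
    def test_default_drops_a_quarter(self):
        values = np.arange(8 * 3).reshape(8, 3).astype(float)
        out = filter_genes(em(values))
        assert out.n_genes == 6  # floor(0.25 * 8) = 2 dropped
        assert out.gene_ids == [f"g{i}" for i in range(2, 8)]

    def test_threshold_zero_keeps_everything(self):
        m = em([[0, 0], [1, 2]])
        out = filter_genes(m, "mean", "threshold", 0)
        assert out.gene_ids == m.gene_ids

    def test_all_zero_gene_removed_by_threshold(self):
        m = em([[0, 0], [5, 5]])
        out = filter_genes(m, "mean", "threshold", 0.1)
        assert out.gene_ids == ["g1"]

    def test_variance_statistic(self):
        m = em([[5, 5], [0, 10]])  # equal means, different variances
        out = filter_genes(m, "variance", "fraction", 0.5)
        assert out.gene_ids == ["g1"]

    def test_fraction_one_rejected(self):
        with pytest.raises(CoexnetError, match="fraction"):
            filter_genes(em([[1, 2]]), "mean", "fraction", 1.0)

    def test_removing_every_gene_rejected(self):
        with pytest.raises(CoexnetError, match="every gene"):
            filter_genes(em([[1, 1]]), "mean", "threshold", 100)

    def test_ties_broken_by_input_order(self):
        m = em([[1, 1], [1, 1], [1, 1], [2, 2]])
        out = filter_genes(m, "mean", "fraction", 0.5)
        assert out.gene_ids == ["g2", "g3"]  # earliest tied genes dropped


class TestLogTransform:
    @pytest.mark.parametrize("value, expected", [(0, 0), (1, 1), (3, 2)])
    def test_log2_with_unit_pseudocount(self, value, expected):
        out = log_transform(em([[value]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_monotone_per_gene(self):
        m = em([[1, 5, 2, 9]])
        out = log_transform(m)
        assert np.array_equal(np.argsort(out.values[0]), np.argsort(m.values[0]))

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(CoexnetError, match="pseudocount"):
            log_transform(em([[1]]), pseudocount=0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_scaling_methods_preserve_within_sample_ratios(seed):
    """Every normalization except quantile is a per-sample rescaling."""
    rng = np.random.default_rng(seed)
    m = em(rng.uniform(1, 100, size=(10, 4)))
    for result in (
        normalize_median(m),
        normalize_median_of_ratios(m)[0],
        normalize_tmm(m)[0],
        normalize_housekeeping(m, ["g0", "g1", "g2"]),
    ):
        ratio = result.values / m.values
        assert np.allclose(ratio, ratio[0:1, :], rtol=1e-10)
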