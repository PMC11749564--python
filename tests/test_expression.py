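"""Count conditioning: filter, size factors, transform, pooling, log2FC, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomsex.containers import CountMatrix
from bloomsex.expression import (
    filter_low_coverage,
    log2fc_over_median,
    pca_group,
    pool_replicates,
    size_factors,
    transform,
)


def _cm(counts: np.ndarray, days, reps=None, genes=None) -> CountMatrix:
    n_samples = counts.shape[1]
    sample_ids = [f"x{i}" for i in range(n_samples)]
    sheet = pd.DataFrame(
        {
            "day": days,
            "replicate": reps if reps is not None else [1] * n_samples,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    idx = genes if genes is not None else [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(pd.DataFrame(counts, index=idx, columns=sample_ids), sheet)


class TestFilterLowCoverage:
    def test_boundary_mean_exactly_five_is_kept(self):
        cm = _cm(np.array([[5, 5, 5, 5], [0, 0, 0, 19]]), days=list("abcd"))
        kept = filter_low_coverage(cm, 5.0)
        assert list(kept.counts.index) == ["g0"]

    def test_day_sum_definition_pools_replicates(self):
        # two replicates of one day: [2,3] pools to 5 -> kept at threshold 5
        cm = _cm(np.array([[2, 3]]), days=["d1", "d1"], reps=[1, 2])
        assert filter_low_coverage(cm, 5.0).counts.shape[0] == 1

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(4, (30, 6))
        days = ["d1", "d1", "d2", "d2", "d3", "d3"]
        cm = _cm(counts, days=days, reps=[1, 2] * 3)
        kept = set(filter_low_coverage(cm, 5.0).counts.index)
        sums = counts[:, 0::2] + counts[:, 1::2]
        want = {f"g{i}" for i in range(30) if sums[i].mean() >= 5.0}
        assert kept == want

    def test_filter_and_pool_commute(self):
        rng = np.random.default_rng(5)
        cm = _cm(rng.poisson(6, (50, 6)), days=["d1", "d1", "d2", "d2", "d3", "d3"], reps=[1, 2] * 3)
        a = pool_replicates(filter_low_coverage(cm, 5.0))
        b = filter_low_coverage(pool_replicates(cm), 5.0)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSizeFactors:
    def test_identical_samples_have_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_forced_values(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        s = size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_fallback_warns_without_all_positive_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(RuntimeWarning, match="total-count"):
            s = size_factors(counts)
        assert np.allclose(s, [1.0, 1.0])


class TestTransform:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"a": [0]})
        assert transform(counts, pd.Series({"a": 1.0})).iloc[0, 0] == 0.0

    def test_1023_maps_to_ten(self):
        counts = pd.DataFrame({"a": [1023]})
        assert transform(counts, pd.Series({"a": 1.0})).iloc[0, 0] == pytest.approx(10.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 10**6), min_size=2, max_size=40))
    def test_monotone_in_counts(self, xs):
        counts = pd.DataFrame({"a": sorted(xs)})
        vals = transform(counts, pd.Series({"a": 1.7})).to_numpy().ravel()
        assert (np.diff(vals) >= 0).all()


class TestPoolReplicates:
    def test_sums_and_conservation(self):
        cm = _cm(np.array([[3, 4, 7]]), days=["d1", "d1", "d2"], reps=[1, 2, 1])
        pooled = pool_replicates(cm)
        assert pooled.counts.loc["g0", "d1"] == 7
        assert pooled.counts.loc["g0", "d2"] == 7  # single replicate passes through
        assert pooled.counts.to_numpy().sum() == cm.counts.to_numpy().sum()


class TestLog2FCOverMedian:
    def test_constant_gene_is_all_zero(self):
        counts = pd.DataFrame([[7, 7, 7]], columns=list("abc"))
        s = pd.Series(1.0, index=list("abc"))
        assert np.allclose(log2fc_over_median(counts, s), 0.0, atol=1e-9)

    def test_spec_example_1_1_1023(self):
        counts = pd.DataFrame([[1, 1, 1023]], columns=list("abc"))
        s = pd.Series(1.0, index=list("abc"))
        lfc = log2fc_over_median(counts, s).to_numpy().ravel()
        assert np.allclose(lfc, [0.0, 0.0, 9.0], atol=1e-12)

    def test_lower_median_for_even_condition_count(self):
        counts = pd.DataFrame([[1, 3, 7, 15]], columns=list("abcd"))
        s = pd.Series(1.0, index=list("abcd"))
        lfc = log2fc_over_median(counts, s).to_numpy().ravel()
        assert lfc[1] == 0.0  # reference is the observed lower median (3)

    def test_swapping_condition_columns_swaps_log2fc_columns(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(40, (20, 4)), columns=list("abcd"))
        s = pd.Series(1.0, index=list("abcd"))
        base = log2fc_over_median(counts, s)
        swapped = log2fc_over_median(counts[["b", "a", "c", "d"]], s)
        pd.testing.assert_frame_equal(base[["b", "a", "c", "d"]], swapped)


class TestPCAGroup:
    def test_duplicate_samples_land_identically_and_variance_sums_to_one(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(100, 1))
        mat = pd.DataFrame(
            np.hstack([base, base, base + rng.normal(size=(100, 1))]),
            columns=["a", "b", "c"],
        )
        pcs, var_frac, _ = pca_group(mat, k=2, seed=0)
        assert np.allclose(pcs.loc["a"], pcs.loc["b"], atol=1e-9)
        assert var_frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_explicit_groups_take_precedence(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        sheet = pd.DataFrame({"group": ["g1", "g1", "g2", "g2"]}, index=list("abcd"))
        _, _, labels = pca_group(mat, k=2, samplesheet=sheet)
        assert list(labels) == ["g1", "g1", "g2", "g2"]

    def test_k_larger_than_samples_rejected(self):
        mat = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError):
            pca_group(mat, k=4)

    def test_recovers_planted_phases(self, bloom):
        from bloomsex.expression import filter_low_coverage as flc, size_factors as sf

        cm, truth = bloom
        cm = flc(cm)
        transformed = transform(cm.counts, sf(cm.counts))
        _, _, labels = pca_group(transformed, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth_groups = cm.samples.loc[transformed.columns, "group"]
        assert adjusted_rand_score(truth_groups, labels) == 1.0
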