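"""The delta statistic, CV, rank-sum comparisons and the resampled null."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from dosevar.dose import fixed_cutoff
from dosevar.variability import (
    Condition,
    compare_groups,
    cv,
    delta,
    delta_matrix,
    delta_multi,
    delta_pools,
    median_null,
)

positive = st.floats(min_value=1e-6, max_value=1e6)


class TestDelta:
    def test_identical_replicates(self):
        assert delta(10, 10) == 0.0

    def test_hand_value(self):
        assert delta(3, 1) == pytest.approx(1.0)

    def test_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            delta(0.0, 0.0)

    @given(positive, positive)
    def test_bounds_symmetry_scale(self, a, b):
        d = delta(a, b)
        assert 0.0 <= d < 2.0
        assert delta(b, a) == d
        assert delta(7.0 * a, 7.0 * b) == pytest.approx(d, rel=1e-9)

    @given(positive, positive)
    def test_pair_identity_with_population_cv(self, a, b):
        """For any pair, delta is exactly twice the divisor-n CV."""
        assert delta(a, b) == pytest.approx(2.0 * cv([a, b]), rel=1e-12, abs=0.0)


class TestDeltaMulti:
    def test_constant_triplicate(self):
        assert delta_multi([5, 5, 5]) == 0.0

    def test_hand_enumeration(self):
        # pairs: (4,4)->0, (4,8)->2/3, (4,8)->2/3; mean = 4/9
        assert delta_multi([4, 4, 8]) == pytest.approx(4.0 / 9.0)

    @given(positive, positive)
    def test_reduces_to_pair(self, a, b):
        assert delta_multi([a, b]) == pytest.approx(delta(a, b))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            delta_multi([4.0])


class TestCv:
    def test_constant(self):
        assert cv([3, 3, 3]) == 0.0

    def test_hand_value(self):
        assert cv([4, 8]) == pytest.approx(1.0 / 3.0)

    @given(st.lists(positive, min_size=2, max_size=8), st.floats(min_value=0.1, max_value=50))
    def test_scale_invariance(self, values, c):
        assert cv([c * v for v in values]) == pytest.approx(cv(values), rel=1e-7, abs=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv([0.0, 0.0])


class TestCompareGroups:
    def test_identical_multisets(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9

    def test_exact_small_sample(self):
        # brute force: 20 equally likely rank assignments, U=0 is one extreme
        # per side -> two-sided p = 2/20 = 0.1
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.statistic == 0.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, 500)
        b = rng.normal(0.3, 1.0, 500)
        assert compare_groups(a, b).p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    @pytest.mark.parametrize("seed,n_a,n_b,shift", [(0, 12, 15, 0.8), (1, 20, 9, 0.0), (2, 30, 30, 0.4)])
    def test_matches_permutation_oracle(self, seed, n_a, n_b, shift):
        """Exact/asymptotic p agrees with a label-permutation oracle."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, n_a)
        b = rng.normal(shift, 1.0, n_b)
        res = compare_groups(a, b)
        p_perm = _permutation_p(a, b, n_perm=10_000, rng=np.random.default_rng(seed + 100))
        mc_err = 3.0 * np.sqrt(max(p_perm, 1e-4) * (1 - min(p_perm, 0.9999)) / 10_000)
        assert abs(res.p_value - p_perm) <= mc_err + 5e-3

    def test_tied_large_sample_close_to_permutation(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 6, 60).astype(float)
        b = rng.integers(0, 6, 60).astype(float)
        res = compare_groups(a, b)
        p_perm = _permutation_p(a, b, n_perm=10_000, rng=np.random.default_rng(103))
        assert abs(res.p_value - p_perm) <= 0.03


def _permutation_p(a, b, n_perm, rng):
    """Independent oracle: permute group labels, compare the rank-sum
    statistic's deviation from its mean."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)).astype(float) + 1.0
    # midranks for ties
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n_a = len(a)
    center = n_a * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - center)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(ranks)
        if abs(ranks[:n_a].sum() - center) >= obs - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestDeltaMatrix:
    def test_toy_values_and_filtering(self, toy_matrix):
        dm = delta_matrix(toy_matrix, Condition(sex="F"), fixed_cutoff(0.68))
        g = dm.gene_ids.get_loc("g2")
        l = dm.line_ids.get_loc("L1")
        assert dm.values[g, l] == pytest.approx(2.0 / 3.0)
        # g3 fails the cutoff in L1 replicate 1 -> unmeasured there
        assert np.isnan(dm.values[dm.gene_ids.get_loc("g3"), l])
        assert dm.values[dm.gene_ids.get_loc("g3"), dm.line_ids.get_loc("L2")] == 0.0

    def test_long_frame_excludes_unmeasured(self, toy_matrix):
        dm = delta_matrix(toy_matrix, Condition(sex="F"), fixed_cutoff(0.68))
        frame = dm.to_frame()
        assert len(frame) == np.isfinite(dm.values).sum()
        assert set(frame.columns) >= {"gene_id", "line_id", "sex", "delta"}


class TestMedianNull:
    def test_single_draw_contract(self, small_analysis):
        res = median_null(small_analysis.matrix, small_analysis.dose_table,
                          Condition(sex="F"), small_analysis.cutoff, B=1, seed=0)
        assert len(res.null_medians) == 1
        assert res.empirical_p in (0.5, 1.0)

    def test_planted_inflation_detected(self, small_analysis):
        res = median_null(small_analysis.matrix, small_analysis.dose_table,
                          Condition(sex="F"), small_analysis.cutoff, B=199, seed=1)
        assert res.observed_median > np.median(res.null_medians)
        assert res.empirical_p == pytest.approx(1.0 / 200.0)

    def test_seed_determinism(self, small_analysis):
        kwargs = dict(condition=Condition(sex="M"), cutoff=small_analysis.cutoff,
                      B=50, seed=7)
        a = median_null(small_analysis.matrix, small_analysis.dose_table, **kwargs)
        b = median_null(small_analysis.matrix, small_analysis.dose_table, **kwargs)
        np.testing.assert_array_equal(a.null_medians, b.null_medians)
        assert a.empirical_p == b.empirical_p

    def test_line_scheme(self, small_analysis):
        res = median_null(small_analysis.matrix, small_analysis.dose_table,
                          Condition(sex="F"), small_analysis.cutoff, B=5,
                          seed=0, scheme="line")
        assert res.scheme == "line"
        assert res.B == len(res.null_medians) > 1
        assert res.observed_median > np.median(res.null_medians)


def test_pools_split(small_analysis):
    dm = delta_matrix(small_analysis.matrix, Condition(sex="F"),
                      small_analysis.cutoff)
    pools = delta_pools(dm, small_analysis.dose_table,
                        spike_in=small_analysis.spike_mask)
    assert pools["one_dose"].size > 0
    assert pools["two_dose"].size > pools["one_dose"].size
    assert pools["spike_in"].size > 0
    # spike-ins carry only technical noise, far below biological noise
    assert np.median(pools["spike_in"]) < np.median(pools["two_dose"])
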