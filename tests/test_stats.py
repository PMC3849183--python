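import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from alphalat import (
    accuracy_rt_trend,
    alpha_lateralization,
    alpha_modulation,
    binomial_ci,
    cluster_permutation_test,
    define_rois,
    make_sensor_array,
    pearson_r,
    rm_anova_2x2,
    timecourse_cluster_test,
    wilcoxon_signed_rank,
)
from alphalat.stats import ROIPair


# ---------------------------------------------------------------------------
# modulation / lateralization algebra
# ---------------------------------------------------------------------------

class TestAlphaModulation:
    def test_worked_example(self):
        assert alpha_modulation(np.array([3.0]), np.array([1.0]))[0] == pytest.approx(0.5)

    def test_equal_powers_give_zero(self):
        for c in (0.1, 1.0, 42.0):
            assert alpha_modulation(np.array([c]), np.array([c]))[0] == 0.0

    def test_antisymmetry_and_bounds_randomized(self, rng):
        a = rng.gamma(2.0, 1.0, (1000,))
        b = rng.gamma(2.0, 1.0, (1000,))
        am = alpha_modulation(a, b)
        np.testing.assert_allclose(am, -alpha_modulation(b, a), atol=1e-12)
        assert (am >= -1).all() and (am <= 1).all()

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="2"):
            alpha_modulation(np.array([1.0, 1.0, 0.0]), np.array([1.0, 1.0, 0.0]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=hnp.arrays(
            np.float64,
            (2, 6),
            elements=st.floats(1e-9, 1e9, allow_nan=False, allow_infinity=False),
        )
    )
    def test_property_bounds_and_antisymmetry(self, p):
        am = alpha_modulation(p[0], p[1])
        assert np.all(np.abs(am) <= 1.0)
        np.testing.assert_allclose(am, -alpha_modulation(p[1], p[0]), atol=1e-12)
        np.testing.assert_allclose(
            alpha_modulation(3.0 * p[0], 3.0 * p[1]), am, atol=1e-12
        )  # scale invariance


class TestAlphaLateralization:
    rois = ROIPair(left_roi=np.array([0, 1]), right_roi=np.array([2, 3]))

    def test_worked_example(self):
        am = np.array([0.06, 0.06, -0.06, -0.06])
        assert alpha_lateralization(am, self.rois) == pytest.approx(0.12)

    def test_zero_map_gives_zero(self):
        assert alpha_lateralization(np.zeros(4), self.rois) == 0.0

    def test_roi_swap_flips_sign(self, rng):
        am = rng.standard_normal((50, 4))
        al = alpha_lateralization(am, self.rois)
        np.testing.assert_allclose(al, -alpha_lateralization(am, self.rois.swapped()))

    def test_empty_roi_rejected(self):
        empty = ROIPair(left_roi=np.array([], dtype=int), right_roi=np.array([0]))
        with pytest.raises(ValueError):
            alpha_lateralization(np.zeros(4), empty)


# ---------------------------------------------------------------------------
# cluster permutation machinery
# ---------------------------------------------------------------------------

def reference_cluster_test(values, adjacency, cluster_alpha=0.05):
    """Independent oracle: exhaustive sign-flip enumeration with explicit
    loops (no shared code with the package implementation)."""
    n, e = values.shape
    thr = sps.t.ppf(1 - cluster_alpha / 2, n - 1)

    def tstats(v):
        return sps.ttest_1samp(v, 0.0, axis=0).statistic

    def clusters_of(t):
        out = []
        for sign in (1, -1):
            mask = sign * t > thr
            unseen = set(np.flatnonzero(mask))
            while unseen:
                stack = [unseen.pop()]
                comp = set(stack)
                while stack:
                    i = stack.pop()
                    for j in np.flatnonzero(adjacency[i]):
                        if mask[j] and j not in comp:
                            comp.add(j)
                            stack.append(j)
                unseen -= comp
                out.append((frozenset(comp), abs(t[list(comp)].sum())))
        return out

    obs = clusters_of(tstats(values))
    null_max = []
    for signs in itertools.product([1, -1], repeat=n):
        flipped = np.asarray(signs)[:, None] * values
        cl = clusters_of(tstats(flipped))
        null_max.append(max((m for _, m in cl), default=0.0))
    null_max = np.asarray(null_max)
    return {c: float(np.mean(null_max >= m)) for c, m in obs}


class TestClusterPermutation:
    def test_all_zero_input_has_no_clusters(self, grid30, rng):
        res = cluster_permutation_test(
            np.zeros((10, 30)), grid30.adjacency, n_perm=100, rng=rng
        )
        assert len(res.clusters) == 0
        assert not res.any_significant()

    def test_strong_block_effect_found_at_min_p(self, grid30, rng):
        values = 0.05 * rng.standard_normal((14, 30))
        block = np.array([8, 9, 10, 11, 12, 13])  # connected posterior sensors
        values[:, block] += 2.0
        res = cluster_permutation_test(values, grid30.adjacency, n_perm=1000, rng=rng)
        sig = res.significant_elements()
        assert set(block) <= set(sig)
        assert res.min_p() == pytest.approx(1 / res.n_permutations)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        sensors = make_sensor_array(8)
        values = rng.standard_normal((8, 8))
        values[:, :3] += 1.0
        res = cluster_permutation_test(values, sensors.adjacency, rng=rng)
        oracle = reference_cluster_test(values, sensors.adjacency)
        assert res.n_permutations == 2**8
        assert len(res.clusters) == len(oracle)
        for comp, mass, p in zip(res.clusters, res.masses, res.p_values):
            key = frozenset(int(i) for i in comp)
            assert key in oracle
            assert p == pytest.approx(oracle[key], abs=1e-12)

    def test_global_sign_flip_leaves_p_values_unchanged(self, grid30):
        rng_a = np.random.default_rng(5)
        values = rng_a.standard_normal((14, 30))
        values[:, 3:7] += 0.8
        res_a = cluster_permutation_test(
            values, grid30.adjacency, n_perm=500, rng=np.random.default_rng(7)
        )
        res_b = cluster_permutation_test(
            -values, grid30.adjacency, n_perm=500, rng=np.random.default_rng(7)
        )
        np.testing.assert_allclose(np.sort(res_a.p_values), np.sort(res_b.p_values))

    def test_input_validation(self, grid30, rng):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((1, 30)), grid30.adjacency, rng=rng)
        with pytest.raises(ValueError):
            cluster_permutation_test(
                np.zeros((5, 30)), grid30.adjacency, n_perm=0, rng=rng
            )
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((5, 4)), grid30.adjacency, rng=rng)


class TestDefineRois:
    def test_planted_lateralized_pattern_recovered(self, grid30, rng):
        maps = 0.05 * rng.standard_normal((14, 30))
        left_post = np.flatnonzero(grid30.posterior & (grid30.hemisphere == "L"))
        right_post = np.flatnonzero(grid30.posterior & (grid30.hemisphere == "R"))
        maps[:, left_post] += 0.5
        maps[:, right_post] -= 0.5
        rois = define_rois(maps, grid30, n_perm=500, rng=rng)
        assert set(left_post) <= set(rois.left_roi)
        assert set(right_post) <= set(rois.right_roi)
        assert maps[:, rois.left_roi].mean() > 0 > maps[:, rois.right_roi].mean()

    def test_null_maps_give_empty_rois(self, grid30):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            rois = define_rois(
                rng.standard_normal((14, 30)), grid30, n_perm=200, rng=rng
            )
            hits += not rois.is_empty
        assert hits <= 2  # nominal 5% false-positive rate


class TestTimecourseCluster:
    times = 0.05 * np.arange(71)  # 0 .. 3.5 s

    def test_identical_series_no_clusters(self, rng):
        a = rng.standard_normal((12, 71))
        res, _ = timecourse_cluster_test(a, a.copy(), self.times, n_perm=200, rng=rng)
        assert len(res.clusters) == 0

    def test_injected_difference_spans_expected_steps(self, rng):
        a = 0.05 * rng.standard_normal((12, 71))
        b = 0.05 * rng.standard_normal((12, 71))
        win_idx = np.flatnonzero((self.times >= 1.0) & (self.times <= 2.5))
        injected = win_idx[12:21]  # steps 12-20 inside the window
        a[:, injected] += 2.0
        res, win_times = timecourse_cluster_test(
            a, b, self.times, n_perm=500, rng=rng
        )
        assert len(res.clusters) >= 1
        best = res.clusters[int(np.argmax(res.masses))]
        assert res.p_values[int(np.argmax(res.masses))] < 0.05
        expected = set(range(12, 21))
        assert expected <= set(best) | {min(best) - 1, max(best) + 1}
        assert set(best) <= set(range(11, 22))


# ---------------------------------------------------------------------------
# parametric battery
# ---------------------------------------------------------------------------

def reference_two_way_rm_anova(v):
    """Brute-force sums-of-squares decomposition for a 2x2 within design."""
    n = v.shape[0]
    out = {}
    # effect contrasts as cell-mean linear combinations
    a = v.mean(axis=2)  # subject x difficulty
    b = v.mean(axis=1)  # subject x eccentricity
    for name, table in (("difficulty", a), ("eccentricity", b)):
        gm = table.mean()
        ss_effect = n * ((table.mean(axis=0) - gm) ** 2).sum()
        resid = table - table.mean(axis=1, keepdims=True) - table.mean(axis=0) + gm
        ss_err = (resid**2).sum()
        out[name] = (ss_effect / 1) / (ss_err / (n - 1))
    inter = v[:, 1, 1] - v[:, 1, 0] - v[:, 0, 1] + v[:, 0, 0]
    out["interaction"] = (inter.mean() / (inter.std(ddof=1) / np.sqrt(n))) ** 2
    return out


class TestRmAnova2x2:
    def test_flat_table_gives_zero_F(self):
        res = rm_anova_2x2(np.full((6, 2, 2), 3.0))
        assert all(res[e].F == 0.0 for e in ("difficulty", "eccentricity", "interaction"))

    def test_F_equals_squared_paired_t(self, rng):
        v = rng.standard_normal((10, 2, 2))
        res = rm_anova_2x2(v)
        t = sps.ttest_rel(v[:, 1, :].mean(axis=1), v[:, 0, :].mean(axis=1))
        assert res["difficulty"].F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res["difficulty"].p == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_sums_of_squares_oracle(self, rng):
        v = rng.standard_normal((12, 2, 2)) + rng.standard_normal((12, 1, 1))
        res = rm_anova_2x2(v)
        ref = reference_two_way_rm_anova(v)
        for effect, F in ref.items():
            assert res[effect].F == pytest.approx(F, rel=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_2x2(np.zeros((2, 2, 2)))


def reference_exact_wilcoxon_p(d):
    """Exact two-sided signed-rank p by full sign enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_symmetric_differences_not_significant(self):
        d = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(d) > 0.5

    def test_all_positive_attains_exact_minimum(self):
        d = np.arange(1.0, 15.0)  # 14 positive differences
        assert wilcoxon_signed_rank(d) == pytest.approx(2 / 2**14)

    def test_mixed_fixture_matches_enumeration_oracle(self, rng):
        d = rng.standard_normal(10) + 0.8
        d = d[d != 0]
        assert wilcoxon_signed_rank(d) == pytest.approx(
            reference_exact_wilcoxon_p(d), rel=1e-9
        )

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(8))


class TestBinomialCI:
    def test_degenerate_bounds(self):
        assert binomial_ci(10, 10)[1] == 1.0
        assert binomial_ci(0, 10)[0] == 0.0

    def test_matches_beta_quantile_oracle(self):
        lo, hi = binomial_ci(75, 100, 0.95)
        ref_lo, ref_hi = proportion_confint(75, 100, alpha=0.05, method="beta")
        assert lo == pytest.approx(ref_lo, abs=1e-10)
        assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 0)
        with pytest.raises(ValueError):
            binomial_ci(5, 3)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_vectors_near_zero(self, rng):
        r, _ = pearson_r(rng.standard_normal(5000), rng.standard_normal(5000))
        assert abs(r) < 0.05

    def test_matches_covariance_formula(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, _ = pearson_r(x, y)
        ref = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestAccuracyRtTrend:
    def test_flat_accuracy_gives_zero_trend(self):
        # accuracy alternates along the RT order, so every quartile bin has
        # the same hit rate and both F statistics vanish
        rts = [np.linspace(0.3, 1.0, 40) for _ in range(6)]
        correct = [np.resize([1, 0], 40) for _ in range(6)]
        res, _ = accuracy_rt_trend(rts, correct)
        assert res["linear_trend"].F == pytest.approx(0.0, abs=1e-12)
        assert res["interval"].F == pytest.approx(0.0, abs=1e-12)

    def test_monotone_accuracy_is_detected(self, rng):
        rts, correct = [], []
        for _ in range(8):
            rt = np.sort(rng.uniform(0.3, 1.5, 40))
            acc = np.concatenate([
                rng.random(10) < p for p in (0.55, 0.7, 0.85, 0.97)
            ])
            rts.append(rt)
            correct.append(acc.astype(float))
        res, table = accuracy_rt_trend(rts, correct)
        assert res["linear_trend"].p < 0.01
        # independent check of the trend contrast against a paired t
        scores = table @ (np.arange(4) - 1.5)
        t = scores.mean() / (scores.std(ddof=1) / np.sqrt(len(scores)))
        assert res["linear_trend"].F == pytest.approx(t**2, rel=1e-9)

    def test_quartile_bins_within_one_trial(self, rng):
        rts = [rng.uniform(0.3, 1.0, 43), rng.uniform(0.3, 1.0, 43)]
        correct = [np.resize([1.0, 0.0], 43)] * 2
        _, table = accuracy_rt_trend(rts, correct)
        assert table.shape == (2, 4)
        sizes = [len(c) for c in np.array_split(np.arange(43), 4)]
        assert max(sizes) - min(sizes) == 1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            accuracy_rt_trend(
                [np.array([0.5, 0.6])] * 2, [np.array([1.0, 0.0])] * 2
            )
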