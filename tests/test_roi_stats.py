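"""ROI summaries and the exact small-sample statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mesovisc.grid import AcquisitionGrid
from mesovisc.inversion import ElastoMaps
from mesovisc.roi import MIN_ROI_AREA_MM2, RoiMask, RoiTooSmallError, summarize_roi
from mesovisc.stats import (
    compare_groups,
    mann_whitney_exact,
    spearman_exact,
    wilcoxon_signed_rank_exact,
)


@pytest.fixture()
def maps_grid():
    grid = AcquisitionGrid((4, 16, 16), (5.0, 2.5, 2.5), (30.0,), 8, 1)
    sws = np.full(grid.shape, 0.8)
    g = np.full(grid.shape, 0.63)
    phi = np.full(grid.shape, 0.46)
    return ElastoMaps(sws, g, phi, grid), grid


class TestSummarizeRoi:
    def test_minimum_area_default_rejects_four_voxels(self, maps_grid):
        # 4 in-plane voxels at 2.5 x 2.5 mm = 25 mm^2 < 31.25 mm^2
        maps, grid = maps_grid
        mask = np.zeros(grid.shape, bool)
        mask[1, 4:6, 4:6] = True
        with pytest.raises(RoiTooSmallError, match="31.25"):
            summarize_roi(maps, RoiMask(mask, "too-small"))
        mask[1, 4, 6] = True  # 5 voxels = 31.25 mm^2: accepted
        summ = summarize_roi(maps, RoiMask(mask, "minimal"))
        assert summ.max_slice_area_mm2 == pytest.approx(MIN_ROI_AREA_MM2)

    def test_constant_map_mean_and_zero_sd(self, maps_grid):
        maps, grid = maps_grid
        mask = np.zeros(grid.shape, bool)
        mask[1:3, 4:10, 4:10] = True
        summ = summarize_roi(maps, RoiMask(mask, "roi"))
        assert summ.mean["sws"] == pytest.approx(0.8)
        assert summ.sd["sws"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mean_and_sample_sd(self, maps_grid):
        maps, grid = maps_grid
        maps.sws[:] = np.nan
        maps.sws[1, 4, 4:9] = [1, 2, 3, 4, 5]
        mask = np.zeros(grid.shape, bool)
        mask[1, 4:9, 4:9] = True  # area 156 mm^2; sws defined on 5 voxels only
        summ = summarize_roi(maps, RoiMask(mask, "roi"))
        assert summ.mean["sws"] == pytest.approx(3.0)
        assert summ.sd["sws"] == pytest.approx(1.5811, abs=1e-4)
        assert summ.n_voxels["sws"] == 5

    def test_fully_undefined_parameter_rejected(self, maps_grid):
        maps, grid = maps_grid
        maps.gstar_kpa[:] = np.nan
        mask = np.zeros(grid.shape, bool)
        mask[1, 2:10, 2:10] = True
        with pytest.raises(RoiTooSmallError, match="no defined voxels"):
            summarize_roi(maps, RoiMask(mask, "roi"))


def _brute_force_mw_p(a, b, convention="inclusive"):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    le = np.mean(ws <= w_obs + 1e-9)
    ge = np.mean(ws >= w_obs - 1e-9)
    pt = np.mean(np.abs(ws - w_obs) < 1e-9)
    if convention == "mid":
        le, ge = le - 0.5 * pt, ge - 0.5 * pt
    return min(1.0, 2 * min(le, ge))


def _brute_force_wilcoxon_p(d, convention="inclusive"):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [(ranks * np.array(signs)).sum() for signs in itertools.product([0, 1], repeat=len(d))]
    )
    le = np.mean(ws <= w_obs + 1e-9)
    ge = np.mean(ws >= w_obs - 1e-9)
    pt = np.mean(np.abs(ws - w_obs) < 1e-9)
    if convention == "mid":
        le, ge = le - 0.5 * pt, ge - 0.5 * pt
    return min(1.0, 2 * min(le, ge))


class TestMannWhitney:
    def test_identical_groups_give_central_u_and_p_one(self):
        r = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(4.5)
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_triplets(self):
        # exact enumeration: one of C(6,3) = 20 arrangements is as extreme,
        # one-sided P(U <= 0) = 1/20, inclusive two-sided p = 0.1
        r = mann_whitney_exact([1, 2, 3], [4, 5, 6], p_convention="inclusive")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 20)
        assert r.exact

    def test_seven_vs_seven_takes_exact_path(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=7)
        assert compare_groups(a, b, method="rank").exact

    @pytest.mark.parametrize("convention", ["inclusive", "mid"])
    def test_matches_brute_force_with_ties(self, rng, convention):
        for _ in range(25):
            n1, n2 = rng.integers(3, 8, 2)
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            r = mann_whitney_exact(a, b, p_convention=convention)
            assert r.p_value == pytest.approx(_brute_force_mw_p(a, b, convention), abs=1e-12)

    def test_all_tied_degenerate(self):
        r = mann_whitney_exact([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.degenerate and r.p_value == 1.0

    def test_large_groups_use_normal_approximation(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        r = mann_whitney_exact(a, b)
        assert not r.exact
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestWilcoxon:
    @pytest.mark.parametrize("convention", ["inclusive", "mid"])
    def test_matches_brute_force(self, rng, convention):
        for _ in range(25):
            n = rng.integers(4, 9)
            d = rng.integers(-4, 5, n).astype(float)
            if np.all(d == 0):
                continue
            r = wilcoxon_signed_rank_exact(d, p_convention=convention)
            assert r.p_value == pytest.approx(_brute_force_wilcoxon_p(d, convention), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank_exact([0.0, 0.0, 0.0])
        assert r.degenerate


class TestCompareGroups:
    def test_normality_gate_routes_to_t_test(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.2, 1, 30)
        r = compare_groups(a, b)
        assert "t-test" in r.test_name

    def test_skewed_data_routes_to_rank_test(self, rng):
        a = rng.lognormal(0, 1.5, 30)
        b = rng.lognormal(0, 1.5, 30)
        r = compare_groups(a, b)
        assert r.test_name == "mann-whitney"

    def test_paired_selects_wilcoxon_or_paired_t(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(0.3, 0.2, 10)
        r = compare_groups(a, b, paired=True)
        assert r.test_name in ("wilcoxon", "paired t-test")

    @given(
        data=st.lists(
            st.integers(min_value=-50, max_value=50), min_size=4, max_size=8
        ),
        shift=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_rank_path_invariant_under_monotone_transform(self, data, shift):
        a = np.asarray(data[: len(data) // 2], float)
        b = np.asarray(data[len(data) // 2 :], float) + shift
        if len(a) < 3 or len(b) < 3 or np.ptp(np.concatenate([a, b])) == 0:
            return
        p1 = compare_groups(a, b, method="rank").p_value
        f = lambda x: np.exp(x / 25.0) + 3 * x  # strictly monotone
        p2 = compare_groups(f(a), f(b), method="rank").p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestSpearman:
    def test_identity_gives_rho_one(self):
        r = spearman_exact([3, 1, 4, 1.5, 9], [3, 1, 4, 1.5, 9])
        assert r.rho == pytest.approx(1.0)

    def test_n6_perfect_concordance_exact_p(self):
        # 720 permutations, exactly one attains rho = 1 per tail
        r = spearman_exact([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert r.rho == pytest.approx(1.0)
        assert r.p_value == pytest.approx(2 / 720)
        assert r.p_value < 0.010  # the reporting threshold of the analysis
        assert r.method == "exact-permutation"

    def test_ties_use_average_ranks(self):
        r = spearman_exact([1, 2, 2, 3], [1, 2, 3, 4])
        ref = sps.spearmanr([1, 2, 2, 3], [1, 2, 3, 4]).statistic
        assert r.rho == pytest.approx(ref)

    def test_zero_variance_degenerate(self):
        r = spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.degenerate

    def test_large_n_asymptotic(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = spearman_exact(x, y)
        assert r.method == "asymptotic"
        assert r.p_value == pytest.approx(sps.spearmanr(x, y).pvalue, rel=1e-9)
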