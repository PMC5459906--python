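"""Group masks, GLM vs closed-form t, effect sizes, cluster correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from rsband.groupstats import (
    ClusterDecision,
    StatResult,
    build_group_mask,
    d_to_t,
    estimate_smoothness,
    glm_group_ttest,
    monte_carlo_cluster_threshold,
    pooled_mask,
    t_to_d,
    threshold_statmap,
)
from rsband.metrics import smooth_gaussian


class TestMasks:
    def test_coverage_boundary_is_inclusive(self):
        """4 of 5 subjects at coverage 0.8 keeps the voxel (>= at boundary)."""
        masks = [np.ones((2, 2, 2), bool) for _ in range(5)]
        masks[0][0, 0, 0] = False  # voxel present in 4/5
        out = build_group_mask(masks, coverage=0.8)
        assert out[0, 0, 0]

    def test_below_coverage_dropped(self):
        masks = [np.ones((2, 2, 2), bool) for _ in range(5)]
        for m in masks[:2]:
            m[0, 0, 0] = False  # present in 3/5
        assert not build_group_mask(masks, coverage=0.8)[0, 0, 0]

    def test_empty_gm_gives_empty_result(self):
        masks = [np.ones((2, 2, 2), bool)] * 3
        out = build_group_mask(masks, gm_mask=np.zeros((2, 2, 2), bool))
        assert not out.any()

    def test_pooled_mask_is_intersection(self, rng):
        masks = [rng.uniform(size=(4, 4, 4)) > 0.3 for _ in range(4)]
        out = pooled_mask(masks)
        for m in masks:
            assert np.all(out <= m)
        np.testing.assert_array_equal(out, np.logical_and.reduce(masks))

    def test_disjoint_masks_pool_to_empty(self):
        a = np.zeros((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        a[0], b[1] = True, True
        assert not pooled_mask([a, b]).any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            pooled_mask([np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool)])


class TestEffectSizeConversion:
    def test_pku1_worked_value(self):
        """d = 0.30 at n = 15/15 corresponds to t = 0.822 (3 decimals)."""
        assert round(d_to_t(0.30, 15, 15), 3) == 0.822

    def test_round_trip_exact(self):
        for t in (-3.2, 0.0, 0.5, 2.7):
            for n1, n2 in ((15, 15), (29, 28), (19, 40)):
                assert d_to_t(t_to_d(t, n1, n2), n1, n2) == pytest.approx(t, abs=1e-12)

    def test_direct_evaluation(self):
        assert t_to_d(2.0, 50, 50) == pytest.approx(0.4, abs=1e-12)
        assert t_to_d(0.0, 10, 20) == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_to_d(1.0, 1, 10)


class TestGlm:
    def test_matches_closed_form_t_without_covariates(self, rng):
        """GLM group-coefficient t must equal the pooled-variance two-sample
        t (scipy oracle) on every voxel."""
        n1, n2, V = 12, 15, 1000
        Y = rng.standard_normal((n1 + n2, V))
        groups = ["ADHD"] * n1 + ["TDC"] * n2
        st = glm_group_ttest(Y, groups)
        want, _ = stats.ttest_ind(Y[:n1], Y[n1:], equal_var=True)
        np.testing.assert_allclose(st.t_map, want, atol=1e-8)
        assert st.df == n1 + n2 - 2

    def test_identical_groups_give_zero_t(self, rng):
        y = rng.standard_normal(50)
        Y = np.tile(y, (8, 1))
        st = glm_group_ttest(Y, ["ADHD"] * 4 + ["TDC"] * 4)
        np.testing.assert_allclose(st.t_map, 0.0, atol=1e-10)

    def test_ses_map_is_scaled_t_map(self, rng):
        Y = rng.standard_normal((20, 64))
        st = glm_group_ttest(Y, ["ADHD"] * 10 + ["TDC"] * 10)
        np.testing.assert_allclose(
            st.ses_map, st.t_map * np.sqrt(20 / 100), atol=1e-12
        )

    def test_sign_convention_adhd_minus_tdc(self):
        Y = np.concatenate([np.full((5, 3), 2.0), np.zeros((5, 3))])
        Y += np.linspace(0, 0.1, 10)[:, None]  # break exact degeneracy
        st = glm_group_ttest(Y, ["ADHD"] * 5 + ["TDC"] * 5)
        assert np.all(st.t_map > 0)

    def test_covariate_adjustment_removes_confounded_difference(self, rng):
        """A group difference wholly carried by a covariate disappears when
        the covariate is in the design."""
        n = 40
        cov = np.r_[np.full(20, 1.0), np.full(20, -1.0)] + rng.normal(0, 0.1, n)
        Y = (3.0 * cov)[:, None] + rng.standard_normal((n, 200))
        groups = ["ADHD"] * 20 + ["TDC"] * 20
        raw = glm_group_ttest(Y, groups)
        adj = glm_group_ttest(Y, groups, covariates=pd.DataFrame({"c": cov}))
        assert np.abs(raw.t_map).mean() > 3 * np.abs(adj.t_map).mean()

    def test_collinear_design_rejected_naming_columns(self, rng):
        Y = rng.standard_normal((10, 5))
        groups = ["ADHD"] * 5 + ["TDC"] * 5
        cov = pd.DataFrame({"dup": [1.0] * 5 + [0.0] * 5})  # duplicates group
        with pytest.raises(ValueError, match="collinear"):
            glm_group_ttest(Y, groups, covariates=cov)


class TestSmoothnessEstimator:
    def test_white_noise_estimates_near_zero(self, rng):
        mask = np.ones((20, 20, 20), bool)
        maps = [rng.standard_normal((20, 20, 20)) for _ in range(4)]
        fwhm = estimate_smoothness(maps, mask, voxel_mm=3.0)
        assert np.all(fwhm <= 1.2 * 3.0)  # at most ~1.2 voxels

    def test_recovers_known_smoothness(self, rng):
        """Noise smoothed to 6 mm FWHM on 3 mm voxels estimates within 20%."""
        mask = np.ones((24, 24, 24), bool)
        est = []
        for _ in range(20):
            m = smooth_gaussian(rng.standard_normal((24, 24, 24)), 6.0, voxel_mm=3.0)
            est.append(estimate_smoothness([m, m], mask, 3.0).mean())
        assert np.mean(est) == pytest.approx(6.0, rel=0.2)

    def test_invariant_to_global_rescaling(self, rng):
        mask = np.ones((16, 16, 16), bool)
        maps = [
            smooth_gaussian(rng.standard_normal((16, 16, 16)), 5.0, voxel_mm=3.0)
            for _ in range(3)
        ]
        a = estimate_smoothness(maps, mask, 3.0)
        b = estimate_smoothness([m * 37.5 for m in maps], mask, 3.0)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestMonteCarloThreshold:
    def test_extreme_voxel_p_gives_k_of_one(self):
        mask = np.ones((10, 10, 10), bool)
        k = monte_carlo_cluster_threshold(mask, 0.0, 1e-6, n_iter=200, seed=0)
        assert k == 1

    def test_deterministic_given_seed(self):
        mask = np.ones((12, 12, 12), bool)
        a = monte_carlo_cluster_threshold(mask, 6.0, 0.05, n_iter=300, seed=5)
        b = monte_carlo_cluster_threshold(mask, 6.0, 0.05, n_iter=300, seed=5)
        assert a == b

    def test_invalid_voxel_p_rejected(self):
        with pytest.raises(ValueError, match="voxel_p"):
            monte_carlo_cluster_threshold(np.ones((5, 5, 5), bool), 6.0, 1.5, n_iter=200)


def _stat_from_t(t_map, mask, n1=15, n2=15, df=28):
    return StatResult(
        t_map=t_map, df=df, ses_map=t_to_d(t_map, n1, n2), mask=mask,
        affine=np.diag([3.0, 3.0, 3.0, 1.0]), n_adhd=n1, n_tdc=n2,
    )


class TestThresholdStatmap:
    def test_all_zero_map_gives_empty_result(self):
        mask = np.ones((8, 8, 8), bool)
        st = _stat_from_t(np.zeros((8, 8, 8)), mask)
        binmap, table = threshold_statmap(st, ClusterDecision(0.05, 10))
        assert not binmap.any() and len(table) == 0

    def test_constructed_blob_reported_once_with_its_size(self):
        mask = np.ones((10, 12, 10), bool)
        t = np.zeros((10, 12, 10))
        t[2:7, 3:9, 2:7] = 5.0  # 5*6*5 = 150 contiguous voxels
        st = _stat_from_t(t, mask)
        binmap, table = threshold_statmap(st, ClusterDecision(0.05, 129))
        assert len(table) == 1
        assert table.loc[0, "n_voxels"] == 150
        assert binmap.sum() == 150
        assert table.loc[0, "sign"] == 1

    def test_cluster_extent_is_strictly_greater_than(self):
        """A cluster of exactly k voxels is rejected (size > k required)."""
        mask = np.ones((131, 1, 1), bool)
        t = np.zeros((131, 1, 1))
        t[:129] = 5.0
        st = _stat_from_t(t, mask)
        _, table = threshold_statmap(st, ClusterDecision(0.05, 129))
        assert len(table) == 0
        t[:130] = 5.0
        _, table = threshold_statmap(_stat_from_t(t, mask), ClusterDecision(0.05, 129))
        assert len(table) == 1 and table.loc[0, "n_voxels"] == 130

    def test_positive_and_negative_clustered_separately(self):
        mask = np.ones((10, 1, 1), bool)
        t = np.zeros((10, 1, 1))
        t[:4] = 5.0
        t[4:8] = -5.0  # adjacent but opposite signs: two clusters
        st = _stat_from_t(t, mask)
        _, table = threshold_statmap(st, ClusterDecision(0.05, 2))
        assert sorted(table["sign"]) == [-1, 1]
        assert list(table["n_voxels"]) == [4, 4]

    def test_ses_and_t_thresholds_select_identical_voxels(self, rng):
        """|d| > 0.30 and |t| > d_to_t(0.30) are the same rule on one map."""
        mask = np.ones((12, 12, 12), bool)
        t = rng.standard_normal((12, 12, 12)) * 1.5
        st = _stat_from_t(t, mask)
        cut_t = d_to_t(0.30, 15, 15)
        sup_t = mask & (np.abs(t) > cut_t)
        sup_d = mask & (np.abs(st.ses_map) > 0.30)
        np.testing.assert_array_equal(sup_t, sup_d)

    def test_connectivity_rule_respected(self):
        # two 2-voxel bars touching only at a corner: one cluster under
        # 26-connectivity, two separate ones under 6-connectivity
        mask = np.ones((4, 4, 4), bool)
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = t[1, 0, 0] = 5.0
        t[2, 1, 1] = t[3, 1, 1] = 5.0  # (1,0,0)->(2,1,1) is a corner contact
        st = _stat_from_t(t, mask)
        _, tab26 = threshold_statmap(st, ClusterDecision(0.05, 1, connectivity=26))
        _, tab6 = threshold_statmap(st, ClusterDecision(0.05, 1, connectivity=6))
        assert len(tab26) == 1 and tab26.loc[0, "n_voxels"] == 4
        assert len(tab6) == 2 and list(tab6["n_voxels"]) == [2, 2]

    def test_empty_mask_rejected(self):
        st = _stat_from_t(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="mask"):
            threshold_statmap(st, ClusterDecision(0.05, 1))
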