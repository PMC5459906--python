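"""ALFF, ReHo, DC against independent oracles, closed forms, and conventions."""

import numpy as np
import pytest
from scipy import stats

from rsband.bands import band_bin_mask
from rsband.core import BoldSeries
from rsband.metrics import compute_alff, compute_dc, compute_reho, smooth_gaussian

TR = 2.0


def _bold(data, tr=TR, smoothed=False):
    b = BoldSeries(np.asarray(data, dtype=float), np.diag([3.0, 3.0, 3.0, 1.0]), tr)
    if smoothed:
        b.meta["history"].append("smooth[6mm]")
    return b


# ---------------------------------------------------------------------------
# independent oracles

def kendalls_w_oracle(courses):
    """Direct evaluation of Kendall's W: ranks per course, rank sums per
    time point, W = (sum R_i^2 - n R̄^2) / ((1/12) K^2 (n^3 - n))."""
    K = len(courses)
    n = len(courses[0])
    ranks = [stats.rankdata(c) for c in courses]
    R = np.sum(ranks, axis=0)
    R_bar = (n + 1) * K / 2.0
    return (np.sum(R**2) - n * R_bar**2) / (K**2 * (n**3 - n) / 12.0)


def reho_oracle(data, mask, neighborhood=27):
    out = np.full(mask.shape, np.nan)
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                courses = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if neighborhood == 7 and abs(dx) + abs(dy) + abs(dz) > 1:
                                continue
                            if neighborhood == 19 and abs(dx) + abs(dy) + abs(dz) > 2:
                                continue
                            i, j, k = x + dx, y + dy, z + dz
                            if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and mask[i, j, k]:
                                courses.append(data[i, j, k])
                if len(courses) >= 2:
                    out[x, y, z] = kendalls_w_oracle(courses)
    return out


def alff_oracle(course, band, tr):
    """Direct DFT evaluation with explicit polynomial detrending."""
    n = len(course)
    t = np.arange(n)
    slope, intercept = np.polyfit(t, course, 1)
    detr = course - (slope * t + intercept)
    amp = 2.0 * np.abs(np.fft.rfft(detr)) / n
    keep = band_bin_mask(n, band, tr)
    return amp[keep].mean()


def exact_correlation_courses(R, T=40, seed=0):
    """Time courses whose *sample* Pearson matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    V = R.shape[0]
    raw = rng.standard_normal((T, V + 1))
    raw -= raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    B = Q[:, 1 : V + 1].T  # orthonormal, zero-mean rows
    B -= B.mean(axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    L = np.linalg.cholesky(R)
    return L @ B


# ---------------------------------------------------------------------------
# ReHo

class TestReHo:
    def test_perfect_concordance_is_one(self):
        """Three identical courses, n=4: rank sums (3,6,9,12) give W = 1."""
        course = np.array([3.0, 1.0, 4.0, 2.0])
        data = np.tile(course, (3, 1, 1, 1))
        W = compute_reho(data, np.ones((3, 1, 1), bool))
        assert W.data[1, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_two_course_example(self):
        """Ranks (1,2,3) and (2,1,3): rank sums (3,3,6), W = 6/8 = 0.75."""
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1.0, 2.0, 3.0]
        data[1, 0, 0] = [2.0, 1.0, 3.0]
        W = compute_reho(data, np.ones((2, 1, 1), bool))
        assert W.data[0, 0, 0] == pytest.approx(0.75, abs=1e-12)
        assert W.data[1, 0, 0] == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_matches_direct_oracle_on_random_volumes(self, rng, neighborhood):
        for _ in range(7 if neighborhood == 27 else 3):
            data = rng.standard_normal((5, 5, 5, 40))
            mask = rng.uniform(size=(5, 5, 5)) > 0.2
            got = compute_reho(data, mask, neighborhood=neighborhood).data
            want = reho_oracle(data, mask, neighborhood)
            np.testing.assert_allclose(got, want, atol=1e-10, equal_nan=True)

    def test_null_mean_near_one_over_K(self, rng):
        """Independent courses, K=27: E[W] = 1/K up to O(1/n)."""
        draws = [
            kendalls_w_oracle(rng.standard_normal((27, 170))) for _ in range(200)
        ]
        assert np.mean(draws) == pytest.approx(1 / 27, abs=0.01)

    def test_invariant_under_monotone_transform(self, rng):
        data = rng.standard_normal((4, 4, 4, 30))
        mask = np.ones((4, 4, 4), bool)
        a = compute_reho(data, mask).data
        b = compute_reho(np.exp(data), mask).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_isolated_voxel_is_missing_not_error(self, rng):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True  # K = 1 < 2
        W = compute_reho(rng.standard_normal((5, 5, 5, 30)), mask)
        assert np.isnan(W.data[2, 2, 2])

    def test_rejects_smoothed_input(self, rng):
        bold = _bold(rng.standard_normal((4, 4, 4, 40)), smoothed=True)
        with pytest.raises(ValueError, match="unsmoothed"):
            compute_reho(bold, np.ones((4, 4, 4), bool))


# ---------------------------------------------------------------------------
# DC

class TestDC:
    def test_three_voxel_worked_example(self):
        """r12=0.5, r13=0.1, r23=0.3 with threshold >= 0.2 gives
        D = (0.5, 0.8, 0.3): the 0.1 edge contributes nothing."""
        R = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 1.0]])
        X = exact_correlation_courses(R)
        data = X.reshape(3, 1, 1, -1)
        D = compute_dc(data, np.ones((3, 1, 1), bool)).data[:, 0, 0]
        np.testing.assert_allclose(D, [0.5, 0.8, 0.3], atol=1e-10)

    def test_orthogonal_courses_give_zero(self):
        X = exact_correlation_courses(np.eye(6))
        D = compute_dc(X.reshape(6, 1, 1, -1), np.ones((6, 1, 1), bool)).data
        np.testing.assert_allclose(D[:, 0, 0], 0.0, atol=1e-10)

    def test_identical_courses_give_M_minus_1(self, rng):
        M = 9
        data = np.tile(rng.standard_normal(50), (M, 1, 1, 1))
        D = compute_dc(data, np.ones((M, 1, 1), bool)).data
        np.testing.assert_allclose(D[:, 0, 0], M - 1, atol=1e-9)

    def test_matches_full_correlation_matrix_oracle(self, rng):
        data = rng.standard_normal((8, 5, 5, 60))
        mask = rng.uniform(size=(8, 5, 5)) > 0.3  # ~140-200 voxels
        got = compute_dc(data, mask, block_size=17).data[mask]
        C = np.corrcoef(data[mask])
        np.fill_diagonal(C, 0.0)
        want = np.where(C >= 0.2, C, 0.0).sum(axis=1)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_threshold_boundary_default_vs_strict(self):
        """A correlation exactly at the threshold is summed by the default
        (>=) rule and dropped by the strict (>) variant. The +/-1 courses
        below have exactly representable correlation 8/16 = 0.5."""
        x1 = np.tile([1.0, -1.0], 8)
        x2 = x1.copy()
        x2[[0, 1, 2, 3]] *= -1  # 4 sign flips (2 each sign): corr = 0.5 exactly
        X = np.stack([x1, x2]).reshape(2, 1, 1, -1)
        mask = np.ones((2, 1, 1), bool)
        assert compute_dc(X, mask, r_threshold=0.5).data[0, 0, 0] == 0.5
        assert compute_dc(X, mask, r_threshold=0.5, strict=True).data[0, 0, 0] == 0.0

    def test_invariant_to_affine_rescaling(self, rng):
        data = rng.standard_normal((4, 4, 4, 40))
        mask = np.ones((4, 4, 4), bool)
        scaled = data * rng.uniform(0.5, 2.0, (4, 4, 4, 1)) + rng.normal(size=(4, 4, 4, 1))
        a = compute_dc(data, mask).data
        b = compute_dc(scaled, mask).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_constant_course_contributes_zero_not_error(self, rng):
        data = rng.standard_normal((3, 1, 1, 30))
        data[0, 0, 0] = 5.0
        D = compute_dc(data, np.ones((3, 1, 1), bool)).data
        assert D[0, 0, 0] == 0.0

    def test_rejects_smoothed_input(self, rng):
        bold = _bold(rng.standard_normal((4, 4, 4, 40)), smoothed=True)
        with pytest.raises(ValueError, match="unsmoothed"):
            compute_dc(bold, np.ones((4, 4, 4), bool))

    def test_pair_cap_enforced(self, rng):
        data = rng.standard_normal((10, 10, 10, 10))
        with pytest.raises(ValueError, match="pairs"):
            compute_dc(data, np.ones((10, 10, 10), bool), max_pairs=1000)


# ---------------------------------------------------------------------------
# ALFF

class TestALFF:
    def test_constant_course_gives_zero(self):
        data = np.full((2, 2, 2, 64), 7.0)
        m = compute_alff(data, "conventional", np.ones((2, 2, 2), bool), tr_seconds=TR)
        np.testing.assert_allclose(m.in_mask(), 0.0, atol=1e-12)

    def test_exact_bin_sinusoid_equals_A_over_m(self):
        """Amplitude-A sinusoid on DFT bin k: 2|X_k|/N = A at that bin, so
        band-mean ALFF is A / (number of in-band bins)."""
        n, A = 160, 3.0
        keep = band_bin_mask(n, "conventional", TR)
        m_bins = keep.sum()
        k = np.flatnonzero(keep)[2]
        t = np.arange(n)
        # phase chosen so the sinusoid is orthogonal to the linear trend,
        # making the internal detrend a no-op
        phi = np.pi + np.pi * k / n
        course = A * np.cos(2 * np.pi * k * t / n + phi)
        data = np.tile(course, (1, 1, 1, 1))
        alff = compute_alff(data, "conventional", np.ones((1, 1, 1), bool), tr_seconds=TR)
        assert alff.data[0, 0, 0] == pytest.approx(A / m_bins, rel=1e-10)

    def test_homogeneity_degree_one(self, rng):
        data = rng.standard_normal((2, 2, 2, 100))
        mask = np.ones((2, 2, 2), bool)
        a = compute_alff(data, "slow4", mask, tr_seconds=TR).in_mask()
        b = compute_alff(2.0 * data, "slow4", mask, tr_seconds=TR).in_mask()
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_matches_direct_dft_oracle(self, rng):
        data = rng.standard_normal((3, 3, 3, 170))
        mask = rng.uniform(size=(3, 3, 3)) > 0.3
        for band in ("conventional", "slow5", "slow2"):
            got = compute_alff(data, band, mask, tr_seconds=TR).data
            for idx in np.argwhere(mask):
                want = alff_oracle(data[tuple(idx)], band, TR)
                assert got[tuple(idx)] == pytest.approx(want, abs=1e-10)

    def test_requires_smoothed_boldseries(self, rng):
        bold = _bold(rng.standard_normal((4, 4, 4, 64)))
        with pytest.raises(ValueError, match="smooth"):
            compute_alff(bold, "conventional", np.ones((4, 4, 4), bool))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            compute_alff(
                rng.standard_normal((2, 2, 2, 64)), "conventional",
                np.zeros((2, 2, 2), bool), tr_seconds=TR,
            )


# ---------------------------------------------------------------------------
# smoothing

class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        img = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(smooth_gaussian(img, 0.0, voxel_mm=3.0), img)

    def test_delta_profile_half_max_at_half_fwhm(self):
        """A 6 mm FWHM kernel on a delta must fall to half its peak at 3 mm
        from the center."""
        img = np.zeros((31, 31, 31))
        img[15, 15, 15] = 1.0
        sm = smooth_gaussian(img, fwhm_mm=6.0, voxel_mm=1.0)
        profile = sm[15:, 15, 15]
        half = profile[0] / 2
        # linear interpolation of the half-max crossing radius (mm)
        above = np.flatnonzero(profile >= half)[-1]
        frac = (profile[above] - half) / (profile[above] - profile[above + 1])
        assert above + frac == pytest.approx(3.0, abs=0.2)

    def test_mask_normalized_smoothing_conserves_interior_mass(self):
        from rsband.core import MetricMap

        mask = np.zeros((20, 20, 20), bool)
        mask[3:17, 3:17, 3:17] = True
        data = np.zeros((20, 20, 20))
        data[9:12, 9:12, 9:12] = 2.0  # interior blob, far from the mask edge
        m = MetricMap(data, "ALFF", "conventional", mask, np.diag([3.0, 3, 3, 1]))
        sm = smooth_gaussian(m, fwhm_mm=6.0)
        assert np.nansum(sm.data[mask]) == pytest.approx(data[mask].sum(), rel=1e-3)

    def test_boldseries_smoothing_tags_history(self, rng):
        bold = _bold(rng.standard_normal((6, 6, 6, 10)))
        sm = smooth_gaussian(bold, 6.0)
        assert any(h.startswith("smooth") for h in sm.history)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_gaussian(rng.standard_normal((4, 4, 4)), -1.0, voxel_mm=3.0)
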