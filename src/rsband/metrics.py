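"""Voxel-wise whole-brain metrics: ALFF, ReHo (Kendall's W), weighted DC.

Smoothing-order conventions are enforced through the BoldSeries processing
history: ALFF is computed on spatially *smoothed* data, while ReHo and DC are
computed on *unsmoothed* data (their maps are smoothed afterwards), because
spatial smoothing would inflate local and long-range correlations
artificially. Passing a plain ndarray bypasses provenance checks — that is
the intended path for oracles and unit tests.

Definitions
-----------
ALFF
    Mean of the single-sided amplitude spectrum 2|X_k|/N over the DFT bins
    falling in the band (0 Hz bin always excluded), after linear detrending.
ReHo
    Kendall's coefficient of concordance W of a voxel's time course with its
    K-1 in-mask nearest neighbours (K = 27, 19 or 7 including the voxel):
    W = (sum_i R_i^2 - n R̄^2) / ((1/12) K^2 (n^3 - n)), where R_i is the
    rank sum at time point i over the K courses and R̄ = (n+1)K/2.
DC
    Weighted degree: D_i = sum_j a_ij over in-mask j != i, with a_ij the
    Pearson correlation kept only when a_ij >= 0.2 (low and negative
    correlations contribute zero).
"""

from __future__ import annotations

import logging
import warnings
from itertools import product

import numpy as np
from scipy import ndimage, signal, stats

from .bands import band_bin_mask, get_band
from .core import MISSING, BoldSeries, MetricMap

__all__ = ["compute_alff", "compute_reho", "compute_dc", "smooth_gaussian"]

log = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_4d(bold, tr_seconds=None, require_smoothed=None):
    """Unpack BoldSeries/ndarray; enforce the smoothing-order convention."""
    if isinstance(bold, BoldSeries):
        smoothed = any(h.startswith("smooth") for h in bold.history)
        if require_smoothed is True and not smoothed:
            raise ValueError(
                "ALFF must be computed on spatially smoothed data; "
                "apply smooth_gaussian first (history: %s)" % bold.history
            )
        if require_smoothed is False and smoothed:
            raise ValueError(
                "ReHo/DC must be computed on unsmoothed data (smooth the metric "
                "map afterwards); history: %s" % bold.history
            )
        return bold.data, bold.tr_seconds, bold.affine
    data = np.asarray(bold, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected 4D data")
    return data, tr_seconds, np.diag([3.0, 3.0, 3.0, 1.0])


def compute_alff(bold, band, mask, tr_seconds: float | None = None) -> MetricMap:
    """Amplitude of low-frequency fluctuation per in-mask voxel.

    Each voxel's course is linearly detrended; ALFF is the mean of the
    normalized amplitude spectrum 2|X_k|/N over bins with f in [low, high)
    (0 Hz excluded always; the Nyquist bin only for a band ending at Nyquist).
    """
    data, tr, affine = _as_4d(bold, tr_seconds, require_smoothed=True)
    if tr is None:
        raise ValueError("tr_seconds required when passing a plain array")
    band = get_band(band)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n = data.shape[3]
    if n < 32:
        raise ValueError(f"need >= 32 time points for ALFF, got {n}")
    keep = band_bin_mask(n, band, tr)
    m_bins = int(keep.sum())
    courses = signal.detrend(data[mask], axis=-1, type="linear")
    amp = 2.0 * np.abs(np.fft.rfft(courses, axis=-1)) / n
    vals = amp[:, keep].mean(axis=1) if m_bins else np.zeros(courses.shape[0])
    out = np.full(mask.shape, MISSING)
    out[mask] = vals
    return MetricMap(out, "ALFF", band.name, mask, affine, smoothed=False)


_NEIGHBOR_OFFSETS = {
    27: [o for o in product((-1, 0, 1), repeat=3)],
    19: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) <= 2],
    7: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) <= 1],
}


def _shift3d(vol: np.ndarray, offset) -> np.ndarray:
    """Shift a 3D(+t) array by an integer offset, zero-filling the border."""
    out = np.zeros_like(vol)
    src = [slice(None)] * vol.ndim
    dst = [slice(None)] * vol.ndim
    for ax, d in enumerate(offset):
        if d == 0:
            continue
        if d > 0:
            dst[ax], src[ax] = slice(d, None), slice(None, -d)
        else:
            dst[ax], src[ax] = slice(None, d), slice(-d, None)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def compute_reho(bold, mask, neighborhood: int = 27, tr_seconds: float | None = None) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    At mask edges the concordance uses the available in-mask neighbours with
    K equal to their actual count; voxels with K < 2 are set to missing.
    Ranks are midranks, without a tie-correction term in the denominator.
    """
    data, _tr, affine = _as_4d(bold, tr_seconds, require_smoothed=False)
    if neighborhood not in _NEIGHBOR_OFFSETS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBOR_OFFSETS)}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match data grid")
    n = data.shape[3]

    ranks = np.zeros_like(data)
    ranks[mask] = stats.rankdata(data[mask], axis=-1)

    rank_sum = np.zeros_like(data)
    k_count = np.zeros(mask.shape)
    fmask = mask.astype(float)
    for off in _NEIGHBOR_OFFSETS[neighborhood]:
        rank_sum += _shift3d(ranks, off)
        k_count += _shift3d(fmask, off)

    K = k_count
    with np.errstate(divide="ignore", invalid="ignore"):
        r_bar = (n + 1) * K / 2.0
        numer = (rank_sum**2).sum(axis=-1) - n * r_bar**2
        denom = K**2 * (n**3 - n) / 12.0
        W = numer / denom
    out = np.full(mask.shape, MISSING)
    valid = mask & (K >= 2)
    out[valid] = np.clip(W[valid], 0.0, 1.0)
    return MetricMap(out, "ReHo", "unspecified", mask, affine, smoothed=False)


def compute_dc(
    bold,
    mask,
    r_threshold: float = 0.2,
    strict: bool = False,
    tr_seconds: float | None = None,
    block_size: int = 2048,
    max_pairs: float = 1e8,
) -> MetricMap:
    """Weighted degree centrality over all in-mask voxel pairs.

    Pearson correlations are computed voxel-against-all-voxels in blocks;
    coefficients below ``r_threshold`` (``<=`` when ``strict``) contribute
    zero, self-correlation is excluded. Constant time courses get all-zero
    correlations (with a logged warning) rather than an error.
    """
    data, _tr, affine = _as_4d(bold, tr_seconds, require_smoothed=False)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    V = int(mask.sum())
    if V * (V - 1) / 2 > max_pairs:
        raise ValueError(f"{V} mask voxels give {V*(V-1)//2:.3g} pairs > {max_pairs:.0g} cap")
    Y = data[mask]
    Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Y, axis=1)
    const = norms == 0
    if const.any():
        log.warning("DC: %d constant time course(s); their correlations set to 0", const.sum())
    norms[const] = 1.0
    Z = Y / norms[:, None]
    Z[const] = 0.0

    D = np.zeros(V)
    for start in range(0, V, block_size):
        block = Z[start : start + block_size] @ Z.T  # (b, V)
        sup = block > r_threshold if strict else block >= r_threshold
        np.putmask(block, ~sup, 0.0)
        # remove self-correlation (suprathreshold by construction unless constant)
        idx = np.arange(start, min(start + block_size, V))
        block[np.arange(len(idx)), idx] = 0.0
        D[idx] = block.sum(axis=1)
    out = np.full(mask.shape, MISSING)
    out[mask] = D
    return MetricMap(out, "DC", "unspecified", mask, affine, smoothed=False)


def smooth_gaussian(obj, fwhm_mm: float = 6.0, voxel_mm=None, mask=None):
    """Spatial Gaussian smoothing (sigma = FWHM / 2*sqrt(2 ln 2) per axis).

    Accepts a BoldSeries (smoothed volume-by-volume, history tagged), a
    MetricMap (mask-normalized: out-of-mask voxels are excluded from the
    kernel support and the result re-masked, avoiding edge bleed), or a raw
    3D/4D array with ``voxel_mm`` given. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")

    if isinstance(obj, BoldSeries):
        vox = obj.voxel_sizes_mm
        if np.any(vox <= 0):
            raise ValueError("non-positive voxel size in affine")
        if fwhm_mm == 0:
            return obj.with_data(obj.data, step="smooth[0mm]")
        sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vox
        sm = ndimage.gaussian_filter(obj.data, sigma=(*sigma_vox, 0.0))
        return obj.with_data(sm, step=f"smooth[{fwhm_mm:g}mm]")

    if isinstance(obj, MetricMap):
        vox = np.sqrt((obj.affine[:3, :3] ** 2).sum(axis=0))
        if np.any(vox <= 0):
            raise ValueError("non-positive voxel size in affine")
        if fwhm_mm == 0:
            return MetricMap(
                obj.data.copy(), obj.metric, obj.band, obj.mask, obj.affine, smoothed=True
            )
        sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vox
        data = np.where(obj.mask, obj.data, 0.0)
        num = ndimage.gaussian_filter(data, sigma=sigma_vox)
        den = ndimage.gaussian_filter(obj.mask.astype(float), sigma=sigma_vox)
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = num / den
        out = np.full(obj.data.shape, MISSING)
        out[obj.mask] = sm[obj.mask]
        return MetricMap(out, obj.metric, obj.band, obj.mask, obj.affine, smoothed=True)

    data = np.asarray(obj, dtype=float)
    if voxel_mm is None:
        raise ValueError("voxel_mm required for raw arrays")
    vox = np.broadcast_to(np.atleast_1d(np.asarray(voxel_mm, dtype=float)), (3,))
    if np.any(vox <= 0):
        raise ValueError("non-positive voxel size")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vox
    if data.ndim == 4:
        return ndimage.gaussian_filter(data, sigma=(*sigma_vox, 0.0))
    if data.ndim != 3:
        raise ValueError("expected 3D or 4D array")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma=sigma_vox)
        den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = num / den
        out = np.full(data.shape, MISSING)
        out[mask] = sm[mask]
        return out
    return ndimage.gaussian_filter(data, sigma=sigma_vox)
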