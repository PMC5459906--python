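"""Synthetic multi-cohort resting-state BOLD data with known injected effects.

Emulates a multi-site pediatric dataset: four cohorts with configurable
ADHD/TDC group sizes, TR 2 s, >= 180 volumes on a 3 mm grid, band-limited
AR(1) noise with spatial smoothness, and group differences injected as

* amplitude effects (band-limited signal added at ROI voxels -> ALFF),
* local-coupling effects (shared course mixed into ROI voxels with per-voxel
  variance preserved -> ReHo),
* hub-connectivity effects (a hub signal shared between a ROI and a random
  fraction of distant voxels -> DC),

each calibrated to a target Cohen's d via an empirical lookup table. IQ and
head-motion (mean FD) covariates are drawn per subject with group-specific
means so the downstream GLM has real nuisance structure to adjust for.

Everything is a pure function of (spec, seed): per-subject random streams are
derived by stable hashing of (master seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import bandpass_fft, get_band
from .core import BoldSeries
from .preprocess import mean_fd_jenkinson

__all__ = [
    "RoiSphere",
    "EffectSpec",
    "CohortSimSpec",
    "SubjectData",
    "CohortDataset",
    "ellipsoid_mask",
    "tissue_masks",
    "simulate_baseline",
    "inject_alff_effect",
    "inject_reho_effect",
    "inject_dc_hub_effect",
    "simulate_motion_params",
    "simulate_cohort",
]

BASELINE_OFFSET = 100.0  # arbitrary physical baseline added to unit-variance noise


# ---------------------------------------------------------------------------
# geometry

def ellipsoid_mask(grid_shape, semi_axes_frac=0.42) -> np.ndarray:
    """Ellipsoid 'brain' centred in the grid; semi-axes as a shape fraction."""
    shape = tuple(int(s) for s in grid_shape)
    semi = np.atleast_1d(np.asarray(semi_axes_frac, dtype=float)) * np.array(shape)
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape)
    r2 = sum(((idx[a] - center[a]) / semi.flat[a % semi.size]) ** 2 for a in range(3))
    return r2 <= 1.0


def tissue_masks(grid_shape):
    """(brain, gm, wm, csf) masks for the phantom.

    The designated WM blob and CSF pocket sit near the -x and +x poles of the
    ellipsoid, leaving the central region gray matter so that effect ROIs
    placed there stay clear of the nuisance-signal masks.
    """
    shape = tuple(int(s) for s in grid_shape)
    brain = ellipsoid_mask(shape, 0.42)
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape)
    wm_c = center + np.array(shape) * np.array([-0.28, 0.0, 0.0])
    wm = sum((idx[a] - wm_c[a]) ** 2 for a in range(3)) <= (0.10 * shape[0]) ** 2
    wm &= brain
    csf_c = center + np.array(shape) * np.array([0.28, 0.0, 0.0])
    csf = sum((idx[a] - csf_c[a]) ** 2 for a in range(3)) <= (0.06 * shape[0]) ** 2
    csf &= brain & ~wm
    gm = brain & ~wm & ~csf
    return brain, gm, wm, csf


@dataclass(frozen=True)
class RoiSphere:
    """Spherical ROI: centre in voxel indices, radius in mm."""

    center_vox: tuple
    radius_mm: float

    def to_mask(self, grid_shape, voxel_mm: float) -> np.ndarray:
        idx = np.indices(tuple(int(s) for s in grid_shape))
        r2 = sum((idx[a] - self.center_vox[a]) ** 2 for a in range(3))
        return r2 * voxel_mm**2 <= self.radius_mm**2


# ---------------------------------------------------------------------------
# specs

@dataclass
class EffectSpec:
    """A designed group difference in one metric at one ROI.

    ``cohens_d`` is the target standardized mean difference of the resulting
    metric at ROI voxels (a recovery target, realized through the calibration
    table), carried by ``group_with_higher_value``.
    """

    kind: str  # alff | reho | dc_hub
    roi: RoiSphere
    cohens_d: float
    band: str = "conventional"
    group_with_higher_value: str = "ADHD"
    partner_fraction: float = 0.3  # dc_hub only

    def __post_init__(self) -> None:
        if self.kind not in ("alff", "reho", "dc_hub"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.group_with_higher_value not in ("ADHD", "TDC"):
            raise ValueError("group_with_higher_value must be ADHD or TDC")
        if not (0 < self.partner_fraction <= 1):
            raise ValueError("partner_fraction must be in (0, 1]")


@dataclass
class CohortSimSpec:
    """One cohort's simulation conditions (sizes, grid, noise, effects)."""

    cohort_id: str
    n_adhd: int
    n_tdc: int
    n_volumes: int = 180
    tr_seconds: float = 2.0
    grid_shape: tuple = (24, 24, 24)
    voxel_mm: float = 3.0
    noise_ar1: float = 0.3
    spatial_fwhm_mm: float = 4.0
    effects: list = field(default_factory=list)
    iq_mean_by_group: dict = field(default_factory=lambda: {"ADHD": 105.0, "TDC": 118.0})
    iq_sd: float = 13.0
    fd_mean_by_group: dict = field(default_factory=lambda: {"ADHD": 0.15, "TDC": 0.12})
    fd_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 180:
            raise ValueError(
                f"n_volumes must be >= 180 (so 10 can be dropped and 170 kept), "
                f"got {self.n_volumes}"
            )
        if not (0 <= self.noise_ar1 < 1):
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.spatial_fwhm_mm < 0:
            raise ValueError("spatial_fwhm_mm must be >= 0")
        if self.n_adhd < 1 or self.n_tdc < 1:
            raise ValueError("both groups need at least one subject")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        a[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_mm
        return a


# ---------------------------------------------------------------------------
# baseline noise

def simulate_baseline(
    rng: np.random.Generator,
    grid_shape,
    n_volumes: int,
    ar1: float = 0.3,
    spatial_fwhm_mm: float = 4.0,
    voxel_mm: float = 3.0,
) -> np.ndarray:
    """AR(1) Gaussian noise, spatially smoothed, unit temporal variance + offset.

    The AR(1) recursion uses innovation SD sqrt(1-rho^2) so the marginal
    variance is 1 before smoothing; after Gaussian spatial smoothing each
    voxel's course is rescaled back to unit temporal SD, keeping injected
    effect scales interpretable as fractions of the baseline SD.
    """
    from scipy import ndimage, signal

    shape = tuple(int(s) for s in grid_shape)
    # float32 throughout: the noise model needs no more precision and the
    # 4D volumes dominate memory traffic
    innov = rng.standard_normal((*shape, n_volumes), dtype=np.float32)
    # AR(1) with innovation SD sqrt(1-rho^2) => unit marginal variance;
    # x_0 drawn from the stationary distribution (plain N(0,1))
    c = np.sqrt(1.0 - ar1**2)
    innov[..., 1:] *= np.float32(c)
    x = signal.lfilter(
        np.array([1.0], np.float32), np.array([1.0, -ar1], np.float32), innov, axis=-1
    )
    if spatial_fwhm_mm > 0:
        sigma_vox = spatial_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / voxel_mm
        x = ndimage.gaussian_filter(x, sigma=(sigma_vox,) * 3 + (0.0,))
        sd = x.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        x /= sd
    return x + np.float32(BASELINE_OFFSET)


# ---------------------------------------------------------------------------
# effect injection

def _band_limited_course(rng, n, band, tr_seconds, size=None) -> np.ndarray:
    """Unit-SD, zero-mean band-limited random course(s), shape (size, n)."""
    shape = (n,) if size is None else (size, n)
    u = bandpass_fft(rng.standard_normal(shape), band, tr_seconds)
    sd = u.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (u - u.mean(axis=-1, keepdims=True)) / sd


def _mix_shared_course(data2d: np.ndarray, u: np.ndarray, coupling: float) -> np.ndarray:
    """Mix shared course u into each row at weight ``coupling``.

    The mixture sqrt(1-c^2)*x_std + c*u is renormalized to each row's
    original mean and SD, so per-voxel temporal variance is preserved exactly
    while inter-voxel correlation rises with c; at c=1 every row becomes a
    copy of u (perfect concordance).
    """
    mu = data2d.mean(axis=1, keepdims=True)
    xd = data2d
    xd = data2d - mu
    sd = xd.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    out = data2d.copy()
    z = xd[ok] / sd[ok]
    m = np.sqrt(1.0 - coupling**2) * z + coupling * u[None, :]
    m = m - m.mean(axis=1, keepdims=True)
    msd = m.std(axis=1, keepdims=True)
    msd[msd == 0] = 1.0
    out[ok] = mu[ok] + sd[ok] * m / msd
    return out


def _roi_mask(roi, grid_shape, voxel_mm) -> np.ndarray:
    if isinstance(roi, RoiSphere):
        return roi.to_mask(grid_shape, voxel_mm)
    m = np.asarray(roi, dtype=bool)
    if m.shape != tuple(grid_shape):
        raise ValueError("ROI mask grid mismatch")
    return m


def inject_alff_effect(
    bold: BoldSeries, roi, band, scale: float, rng: np.random.Generator
) -> BoldSeries:
    """Add independent band-limited signal of SD ``scale`` at ROI voxels.

    The added signal has a flat spectrum inside the band and zero outside, so
    the amplitude increase is confined to the target band; voxels outside the
    ROI are bit-identical to the input.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    band = get_band(band)
    band.validate_for_tr(bold.tr_seconds)
    if scale == 0:
        return bold
    roi_m = _roi_mask(roi, bold.grid_shape, float(bold.voxel_sizes_mm[0]))
    n_roi = int(roi_m.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    sig = scale * _band_limited_course(rng, bold.n_volumes, band, bold.tr_seconds, size=n_roi)
    data = bold.data.copy()
    data[roi_m] += sig
    return bold.with_data(data, step=f"inject_alff[{band.name}]")


def inject_reho_effect(
    bold: BoldSeries,
    roi,
    coupling: float,
    rng: np.random.Generator,
    band="conventional",
) -> BoldSeries:
    """Mix one shared band-limited course into all ROI voxels.

    ``coupling`` in [0, 1] sets the mixing weight; per-voxel variance is
    renormalized so the effect is pure synchrony, not amplitude. coupling=0
    returns the input unchanged; coupling=1 makes all ROI courses identical
    up to their own mean/SD (Kendall's W = 1).
    """
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must be in [0, 1]")
    if coupling == 0:
        return bold
    roi_m = _roi_mask(roi, bold.grid_shape, float(bold.voxel_sizes_mm[0]))
    if not roi_m.any():
        raise ValueError("empty ROI")
    u = _band_limited_course(rng, bold.n_volumes, band, bold.tr_seconds)
    data = bold.data.copy()
    data[roi_m] = _mix_shared_course(data[roi_m], u, coupling)
    return bold.with_data(data, step="inject_reho")


def inject_dc_hub_effect(
    bold: BoldSeries,
    hub_roi,
    partner_fraction: float,
    coupling: float,
    rng: np.random.Generator,
    brain_mask: np.ndarray | None = None,
    band="conventional",
) -> BoldSeries:
    """Make a ROI a connectivity hub: share a signal with distant partners.

    A hub course is mixed (weight ``coupling``, variance preserved) into the
    hub ROI and into a random ``partner_fraction`` of non-hub in-mask voxels,
    raising the hub's suprathreshold correlation mass (weighted degree).
    """
    if not (0 < partner_fraction <= 1):
        raise ValueError("partner_fraction must be in (0, 1]")
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must be in [0, 1]")
    hub_m = _roi_mask(hub_roi, bold.grid_shape, float(bold.voxel_sizes_mm[0]))
    if not hub_m.any():
        raise ValueError("empty hub ROI")
    if brain_mask is None:
        brain_mask = np.ones(bold.grid_shape, dtype=bool)
    candidates = np.flatnonzero(np.asarray(brain_mask, dtype=bool).ravel() & ~hub_m.ravel())
    n_partners = int(round(partner_fraction * candidates.size))
    partners = rng.choice(candidates, size=n_partners, replace=False)
    if coupling == 0:
        return bold
    target = hub_m.copy()
    target.ravel()[partners] = True
    u = _band_limited_course(rng, bold.n_volumes, band, bold.tr_seconds)
    data = bold.data.copy()
    data[target] = _mix_shared_course(data[target], u, coupling)
    return bold.with_data(data, step="inject_dc_hub")


# ---------------------------------------------------------------------------
# motion

# unit-severity random-walk step SDs: 0.02 mm translations, 2e-4 rad rotations
_MOTION_STEP = np.array([0.02, 0.02, 0.02, 2e-4, 2e-4, 2e-4])


def simulate_motion_params(n_volumes: int, severity: float, seed) -> np.ndarray:
    """Random-walk rigid-body motion: 3 translations (mm), 3 rotations (rad).

    ``severity`` scales the per-frame step size; 0 gives an all-zero table
    (mean FD = 0 downstream).
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes for a motion table")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6)) * _MOTION_STEP * severity
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _motion_for_target_fd(n_volumes: int, target_fd: float, rng) -> np.ndarray:
    """Motion table whose Jenkinson mean FD equals ``target_fd`` exactly-ish.

    A unit-severity walk is generated and rescaled; FD is linear in the
    parameters to first order, so one rescale lands on target.
    """
    base = simulate_motion_params(n_volumes, 1.0, rng)
    fd0 = mean_fd_jenkinson(base)
    if fd0 == 0 or target_fd <= 0:
        return np.zeros_like(base)
    return base * (target_fd / fd0)


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class SubjectData:
    subject_id: str
    group: str
    bold: BoldSeries
    motion: np.ndarray
    iq: float
    mean_fd: float
    mask: np.ndarray


@dataclass
class CohortDataset:
    cohort_id: str
    subjects: list
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    participants: pd.DataFrame
    spec: CohortSimSpec


def _effect_param(effect: EffectSpec):
    """Injection parameter realizing |cohens_d|, via the calibration table."""
    from .calibration import lookup_param

    return lookup_param(effect.kind, abs(effect.cohens_d))


def simulate_cohort(spec: CohortSimSpec, calibrated: bool = True) -> CohortDataset:
    """Generate one cohort: per-subject BOLD + motion + participant rows.

    Deterministic given ``spec.seed``. Effects are applied to the subjects of
    each effect's higher-value group, with injection strength taken from the
    calibration table (or used as the raw parameter when ``calibrated`` is
    False and ``EffectSpec.cohens_d`` is interpreted directly as scale /
    coupling).
    """
    brain, gm, wm, csf = tissue_masks(spec.grid_shape)
    for eff in spec.effects:
        roi_m = _roi_mask(eff.roi, spec.grid_shape, spec.voxel_mm)
        if not roi_m.any():
            raise ValueError(f"effect ROI is empty on grid {spec.grid_shape}")
        if (roi_m & ~brain).any():
            raise ValueError("effect ROI extends outside the brain mask")

    groups = ["ADHD"] * spec.n_adhd + ["TDC"] * spec.n_tdc
    subjects = []
    rows = []
    affine = spec.affine
    for i, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        data = simulate_baseline(
            rng,
            spec.grid_shape,
            spec.n_volumes,
            ar1=spec.noise_ar1,
            spatial_fwhm_mm=spec.spatial_fwhm_mm,
            voxel_mm=spec.voxel_mm,
        )
        bold = BoldSeries(
            data,
            affine,
            spec.tr_seconds,
            meta={"subject": f"{spec.cohort_id}-{i:03d}", "cohort": spec.cohort_id},
        )
        for eff in spec.effects:
            if group != eff.group_with_higher_value:
                continue
            param = _effect_param(eff) if calibrated else abs(eff.cohens_d)
            if eff.kind == "alff":
                bold = inject_alff_effect(bold, eff.roi, eff.band, param, rng)
            elif eff.kind == "reho":
                bold = inject_reho_effect(bold, eff.roi, param, rng, band=eff.band)
            else:
                bold = inject_dc_hub_effect(
                    bold, eff.roi, eff.partner_fraction, param, rng,
                    brain_mask=brain, band=eff.band,
                )
        iq = float(rng.normal(spec.iq_mean_by_group[group], spec.iq_sd))
        target_fd = max(
            float(rng.normal(spec.fd_mean_by_group[group], spec.fd_sd)), 0.01
        )
        motion = _motion_for_target_fd(spec.n_volumes, target_fd, rng)
        sid = f"sub-{spec.cohort_id}{i:03d}"
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                bold=bold,
                motion=motion,
                iq=iq,
                mean_fd=mean_fd_jenkinson(motion),
                mask=brain.copy(),
            )
        )
        rows.append(
            {
                "participant_id": sid,
                "cohort": spec.cohort_id,
                "group": group,
                "iq": iq,
                "sex": "M",
            }
        )
    return CohortDataset(
        cohort_id=spec.cohort_id,
        subjects=subjects,
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        participants=pd.DataFrame(rows),
        spec=spec,
    )
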