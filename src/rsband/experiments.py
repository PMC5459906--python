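"""Reusable simulation experiments quantifying pipeline operating behavior.

These drive the generator + metric + group-statistics stack end to end:

* ``null_cluster_analysis`` — false-positive calibration: effect-free cohorts
  analyzed with Monte-Carlo cluster-extent correction; reports how many runs
  produce any surviving cluster.
* ``effect_recovery`` — power/recovery: a known ALFF effect of Cohen's d is
  injected and the fraction of seeds in which it survives correction, plus
  the mean recovered SES at the ROI, is measured.
* ``mc_ordering`` — the cluster-extent threshold k over a grid of smoothness
  and voxel-p settings (k must be non-decreasing in both).
* ``overlap_regimes`` — the two qualitative regimes of cross-cohort
  consistency: disjoint per-cohort effects (empty 4-cohort overlap) versus
  identical strong effects (non-empty overlap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consistency import dice_overlap, overlap_count
from .groupstats import (
    ClusterDecision,
    build_group_mask,
    estimate_smoothness,
    glm_group_ttest,
    monte_carlo_cluster_threshold,
    threshold_statmap,
)
from .pipeline import subject_metric_map
from .simulate import CohortSimSpec, EffectSpec, RoiSphere, simulate_cohort

__all__ = [
    "analyze_cohort",
    "null_cluster_analysis",
    "effect_recovery",
    "mc_ordering",
    "overlap_regimes",
]


def _derived_seed(*parts) -> int:
    """Stable child seed from mixed int/str parts (strings crc32-hashed)."""
    import zlib

    nums = tuple(
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    )
    return int(np.random.SeedSequence(nums).generate_state(1)[0] % (2**31))


def analyze_cohort(dataset, metric: str = "ALFF", band: str = "conventional"):
    """Group GLM (IQ + mean-FD covariates) for one cohort; returns (stat, mask)."""
    maps = [subject_metric_map(s, metric, band, dataset) for s in dataset.subjects]
    gmask = build_group_mask(
        [s.mask for s in dataset.subjects], 0.8, dataset.gm_mask
    )
    cov = pd.DataFrame(
        {
            "iq": [s.iq for s in dataset.subjects],
            "mean_fd": [s.mean_fd for s in dataset.subjects],
        }
    )
    stat = glm_group_ttest(
        maps,
        [s.group for s in dataset.subjects],
        covariates=cov,
        mask=gmask,
        affine=dataset.spec.affine,
    )
    return stat, gmask


def _cluster_k_from_stat(stat, mask, voxel_mm, voxel_p, corrected_p, mc_iter, seed):
    resid_maps = []
    for i in range(min(8, stat.residuals.shape[0])):
        rm = np.zeros(mask.shape)
        rm[mask] = stat.residuals[i]
        resid_maps.append(rm)
    fwhm = estimate_smoothness(resid_maps, mask, voxel_mm)
    k = monte_carlo_cluster_threshold(
        mask, fwhm, voxel_p, corrected_p, n_iter=mc_iter, seed=seed, voxel_mm=voxel_mm
    )
    return k, fwhm


def null_cluster_analysis(
    n_runs: int = 100,
    n_per_group: int = 20,
    grid_shape=(20, 20, 20),
    band: str = "conventional",
    metric: str = "ALFF",
    voxel_p: float = 0.05,
    corrected_p: float = 0.05,
    mc_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Effect-free group analyses: how often does any cluster survive?

    The cluster-extent threshold k is calibrated once, from the first run's
    residual smoothness: with no effects every run shares the same noise
    model, so the smoothness (hence k) is common by construction.
    """
    n_with_cluster = 0
    k = None
    for run in range(n_runs):
        spec = CohortSimSpec(
            "null", n_per_group, n_per_group,
            grid_shape=tuple(grid_shape), seed=_derived_seed(seed, run),
        )
        ds = simulate_cohort(spec)
        stat, gmask = analyze_cohort(ds, metric, band)
        if k is None:
            k, fwhm = _cluster_k_from_stat(
                stat, gmask, spec.voxel_mm, voxel_p, corrected_p, mc_iter,
                _derived_seed(seed, "mc"),
            )
        decision = ClusterDecision(voxel_p, max(k, 1), 26, corrected_p)
        _, table = threshold_statmap(stat, decision, mode="t_based")
        if len(table):
            n_with_cluster += 1
    return {
        "n_runs": n_runs,
        "n_with_cluster": n_with_cluster,
        "rate": n_with_cluster / n_runs,
        "cluster_k": int(k),
        "residual_fwhm_mm": [float(f) for f in fwhm],
    }


def effect_recovery(
    cohens_d: float = 1.2,
    n_seeds: int = 20,
    n_per_group: int = 20,
    grid_shape=(20, 20, 20),
    roi_radius_mm: float = 11.0,
    band: str = "conventional",
    voxel_p: float = 0.05,
    corrected_p: float = 0.05,
    mc_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Inject an ALFF effect of known d; measure detection rate + recovered SES.

    Detection = at least one corrected surviving cluster overlapping the ROI.
    The recovered SES is the ROI-mean of the Cohen's-d map, averaged over
    seeds. The cluster threshold k is calibrated once from the first seed's
    residuals (identical noise conditions across seeds).
    """
    center = tuple(int(s) // 2 for s in grid_shape)
    roi = RoiSphere(center, roi_radius_mm)
    detected = 0
    ses_means = []
    k = None
    for i in range(n_seeds):
        spec = CohortSimSpec(
            "rec", n_per_group, n_per_group, grid_shape=tuple(grid_shape),
            effects=[EffectSpec("alff", roi, cohens_d, band=band)],
            seed=_derived_seed(seed, 77, i),
        )
        ds = simulate_cohort(spec)
        stat, gmask = analyze_cohort(ds, "ALFF", band)
        if k is None:
            k, _ = _cluster_k_from_stat(
                stat, gmask, spec.voxel_mm, voxel_p, corrected_p, mc_iter,
                _derived_seed(seed, "mc"),
            )
        decision = ClusterDecision(voxel_p, max(k, 1), 26, corrected_p)
        binmap, _ = threshold_statmap(stat, decision, mode="t_based")
        roi_m = roi.to_mask(spec.grid_shape, spec.voxel_mm) & gmask
        if (binmap & roi_m).any():
            detected += 1
        ses_means.append(float(np.nanmean(stat.ses_map[roi_m])))
    return {
        "n_seeds": n_seeds,
        "detection_rate": detected / n_seeds,
        "mean_ses": float(np.mean(ses_means)),
        "target_d": cohens_d,
        "cluster_k": int(k),
    }


def mc_ordering(
    grid_shape=(20, 20, 20),
    fwhms=(3.0, 6.0, 9.0),
    voxel_ps=(0.005, 0.02, 0.05),
    n_iter: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Cluster threshold k over an FWHM x voxel-p grid (same noise seed).

    Common random numbers across cells isolate the setting effect. The
    voxel-p grid stays at or below 0.05: much beyond that the two-tailed
    suprathreshold set approaches the percolation regime, where the
    max-cluster-size tail quantile is too noisy at moderate iteration counts
    for the theoretical ordering to be visible.
    """
    from .simulate import ellipsoid_mask

    mask = ellipsoid_mask(grid_shape)
    ks = np.zeros((len(fwhms), len(voxel_ps)), dtype=int)
    for i, f in enumerate(fwhms):
        for j, p in enumerate(voxel_ps):
            ks[i, j] = monte_carlo_cluster_threshold(
                mask, f, p, n_iter=n_iter, seed=_derived_seed(seed, "ord"), voxel_mm=3.0
            )
    return ks


def _four_cohort_study(rois, cohens_d, n_per_group, grid_shape, seed, voxel_p, mc_iter):
    """Analyze 4 cohorts whose effect ROI is given per cohort; binarized maps."""
    binmaps = []
    k = None
    for ci, roi in enumerate(rois):
        spec = CohortSimSpec(
            f"c{ci + 1}", n_per_group, n_per_group, grid_shape=tuple(grid_shape),
            effects=[EffectSpec("alff", roi, cohens_d)],
            seed=_derived_seed(seed, "cohort", ci),
        )
        ds = simulate_cohort(spec)
        stat, gmask = analyze_cohort(ds, "ALFF", "conventional")
        if k is None:
            k, _ = _cluster_k_from_stat(
                stat, gmask, spec.voxel_mm, voxel_p, 0.05, mc_iter,
                _derived_seed(seed, "mc"),
            )
        decision = ClusterDecision(voxel_p, max(k, 1), 26)
        binmap, _ = threshold_statmap(stat, decision, mode="t_based")
        binmaps.append(binmap)
    return binmaps


def overlap_regimes(
    cohens_d: float = 1.5,
    n_per_group: int = 14,
    grid_shape=(20, 20, 20),
    voxel_p: float = 0.05,
    mc_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """The two consistency regimes: disjoint vs identical per-cohort effects.

    With per-cohort ROIs placed disjointly the 4-cohort overlap should be
    empty (Dice ~ 0); with one shared ROI and a large effect it should not.
    """
    c = tuple(int(s) // 2 for s in grid_shape)
    off = max(3, int(grid_shape[1] // 5))
    disjoint_rois = [
        RoiSphere((c[0], c[1] + off, c[2]), 7.0),
        RoiSphere((c[0], c[1] - off, c[2]), 7.0),
        RoiSphere((c[0], c[1], c[2] + off), 7.0),
        RoiSphere((c[0], c[1], c[2] - off), 7.0),
    ]
    identical_rois = [RoiSphere(c, 11.0)] * 4
    out = {}
    for name, rois in (("disjoint", disjoint_rois), ("identical", identical_rois)):
        binmaps = _four_cohort_study(
            rois, cohens_d, n_per_group, grid_shape, _derived_seed(seed, name),
            voxel_p, mc_iter,
        )
        count = overlap_count(binmaps)
        out[name] = {
            "n_voxels_all4": int((count >= 4).sum()),
            "max_overlap": int(count.max()),
            "dice": dice_overlap(binmaps),
        }
    return out
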