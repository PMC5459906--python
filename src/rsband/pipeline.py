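"""Study orchestration: config, per-subject metric pipeline, full study run.

``subject_metric_map`` is the canonical per-subject path every analysis uses:
truncate -> nuisance regression (trend, Friston-24, WM, CSF) -> metric with
the correct smoothing order (ALFF on smoothed data; ReHo/DC on unsmoothed
band-filtered data with the metric map smoothed afterwards).

``run_study`` binds everything into the end-to-end experiment: per-cohort and
pooled group GLMs for each metric x band, three thresholding regimes (strict
Monte-Carlo cluster extent, lenient k=10, SES cuts), cross-cohort overlap
reports, and a JSON manifest recording every seed, threshold and output hash.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bands import bandpass_fft, get_band
from .consistency import OverlapReport
from .core import BoldSeries, MetricMap
from .groupstats import (
    ClusterDecision,
    build_group_mask,
    d_to_t,
    estimate_smoothness,
    glm_group_ttest,
    monte_carlo_cluster_threshold,
    pooled_mask,
    threshold_statmap,
)
from .metrics import compute_alff, compute_dc, compute_reho, smooth_gaussian
from .preprocess import build_confounds, extract_tissue_signal, regress_nuisance, truncate_volumes
from .simulate import CohortSimSpec, EffectSpec, RoiSphere, simulate_cohort

__all__ = ["StudyConfig", "subject_metric_map", "run_study"]

METRICS = ("ALFF", "ReHo", "DC")


def subject_metric_map(
    sub,
    metric: str,
    band,
    dataset=None,
    drop_first: int = 10,
    keep: int = 170,
    smooth_fwhm_mm: float = 6.0,
    use_confounds: bool = True,
) -> MetricMap:
    """One subject's metric map in one band, with the standard preprocessing."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    band = get_band(band)
    bold = truncate_volumes(sub.bold, drop_first, keep)
    if use_confounds:
        motion = np.asarray(sub.motion)[drop_first : drop_first + keep]
        wm = csf = None
        if dataset is not None:
            wm = extract_tissue_signal(bold, dataset.wm_mask)
            csf = extract_tissue_signal(bold, dataset.csf_mask)
        conf = build_confounds(keep, motion6=motion, wm_signal=wm, csf_signal=csf)
        bold = regress_nuisance(bold, conf)
    mask = sub.mask
    if metric == "ALFF":
        sm = smooth_gaussian(bold, fwhm_mm=smooth_fwhm_mm)
        return compute_alff(sm, band, mask)
    filt = bold.with_data(
        bandpass_fft(bold.data, band, bold.tr_seconds), step=f"bandpass[{band.name}]"
    )
    if metric == "ReHo":
        m = compute_reho(filt, mask)
    else:
        m = compute_dc(filt, mask)
    m = MetricMap(m.data, m.metric, band.name, m.mask, sub.bold.affine)
    return smooth_gaussian(m, fwhm_mm=smooth_fwhm_mm)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class StudyConfig:
    """Declarative description of one end-to-end study run."""

    cohorts: list  # list of dicts accepted by CohortSimSpec (roi given as dict)
    bands: list = field(default_factory=lambda: ["conventional"])
    metrics: list = field(default_factory=lambda: list(METRICS))
    voxel_p: float = 0.05
    corrected_p: float = 0.05
    lenient_k: int = 10
    ses_cuts: list = field(default_factory=lambda: [0.3, 0.5])
    mc_n_iter: int = 1000
    connectivity: int = 26
    drop_first: int = 10
    keep: int = 170
    smooth_fwhm_mm: float = 6.0
    coverage: float = 0.8
    output_dir: str = "study_out"
    master_seed: int = 0

    def __post_init__(self) -> None:
        for b in self.bands:
            get_band(b)  # fail fast on unknown band names
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if not self.cohorts:
            raise ValueError("at least one cohort required")

    def cohort_specs(self) -> list:
        specs = []
        for i, c in enumerate(self.cohorts):
            c = dict(c)
            effects = []
            for e in c.pop("effects", []):
                e = dict(e)
                roi = e.pop("roi")
                e["roi"] = RoiSphere(tuple(roi["center_vox"]), float(roi["radius_mm"]))
                effects.append(EffectSpec(**e))
            c.setdefault("seed", int(np.random.SeedSequence((self.master_seed, i)).generate_state(1)[0] % (2**31)))
            if "grid_shape" in c:
                c["grid_shape"] = tuple(c["grid_shape"])
            specs.append(CohortSimSpec(effects=effects, **c))
        return specs

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# study runner

def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_study(config: StudyConfig, write_nifti_outputs: bool = False) -> dict:
    """Run the whole experiment; return the result tree (also written to disk).

    For every metric x band: per-cohort and pooled GLMs (IQ + mean FD
    covariates, cohort dummies when pooled), strict / lenient / SES
    thresholding, and an OverlapReport across cohorts. A manifest with every
    seed, derived cluster threshold k and data hash goes to
    ``output_dir/manifest.json``. Deterministic given the config.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    specs = config.cohort_specs()
    datasets = [simulate_cohort(s) for s in specs]
    affine = specs[0].affine

    cohort_masks = {
        d.cohort_id: build_group_mask(
            [s.mask for s in d.subjects], config.coverage, d.gm_mask
        )
        for d in datasets
    }
    pmask = (
        pooled_mask(list(cohort_masks.values()))
        if len(datasets) > 1
        else next(iter(cohort_masks.values()))
    )

    manifest = {
        "config": asdict(config),
        "seeds": {d.cohort_id: d.spec.seed for d in datasets},
        "analyses": {},
    }
    results = {"datasets": datasets, "cohort_masks": cohort_masks, "pooled_mask": pmask,
               "stats": {}, "thresholded": {}, "overlap": {}, "manifest": manifest}

    for metric in config.metrics:
        for band in config.bands:
            key = f"{metric}_{get_band(band).name}"
            maps = {}
            for d in datasets:
                maps[d.cohort_id] = [
                    subject_metric_map(
                        s, metric, band, d,
                        drop_first=config.drop_first, keep=config.keep,
                        smooth_fwhm_mm=config.smooth_fwhm_mm,
                    )
                    for s in d.subjects
                ]
            stats = {}
            for d in datasets:
                cov = pd.DataFrame(
                    {"iq": [s.iq for s in d.subjects], "mean_fd": [s.mean_fd for s in d.subjects]}
                )
                stats[d.cohort_id] = glm_group_ttest(
                    maps[d.cohort_id], [s.group for s in d.subjects],
                    covariates=cov, mask=cohort_masks[d.cohort_id], affine=affine,
                )
            # pooled analysis with cohort dummies
            all_maps, all_groups, cov_rows = [], [], []
            for ci, d in enumerate(datasets):
                for s, m in zip(d.subjects, maps[d.cohort_id]):
                    all_maps.append(m)
                    all_groups.append(s.group)
                    row = {"iq": s.iq, "mean_fd": s.mean_fd}
                    for cj in range(1, len(datasets)):
                        row[f"cohort_{datasets[cj].cohort_id}"] = float(ci == cj)
                    cov_rows.append(row)
            pooled_stat = glm_group_ttest(
                all_maps, all_groups, covariates=pd.DataFrame(cov_rows),
                mask=pmask, affine=affine,
            )
            stats["pooled"] = pooled_stat

            # cluster-extent calibration from pooled residual smoothness
            resid_maps = []
            for i in range(min(8, pooled_stat.residuals.shape[0])):
                rm = np.zeros(pmask.shape)
                rm[pmask] = pooled_stat.residuals[i]
                resid_maps.append(rm)
            fwhm = estimate_smoothness(resid_maps, pmask, specs[0].voxel_mm)
            ks = {}
            for name, m in [("pooled", pmask)] + list(cohort_masks.items()):
                ks[name] = monte_carlo_cluster_threshold(
                    m, fwhm, config.voxel_p, config.corrected_p,
                    n_iter=config.mc_n_iter, connectivity=config.connectivity,
                    seed=int(np.random.SeedSequence((config.master_seed, 999)).generate_state(1)[0] % (2**31)),
                    voxel_mm=specs[0].voxel_mm,
                )

            thresholded = {}
            for name, st in stats.items():
                k = ks.get(name, ks["pooled"])
                regimes = {
                    "strict": (ClusterDecision(config.voxel_p, max(k, 1), config.connectivity), "t_based", None),
                    "lenient": (ClusterDecision(config.voxel_p, config.lenient_k, config.connectivity), "t_based", None),
                }
                for cut in config.ses_cuts:
                    regimes[f"ses{cut:g}"] = (
                        ClusterDecision(config.voxel_p, max(k, 1), config.connectivity),
                        "ses_based", cut,
                    )
                out = {}
                for rname, (dec, mode, cut) in regimes.items():
                    binmap, table = threshold_statmap(
                        st, dec, mode=mode, ses_cut=cut if cut is not None else 0.3
                    )
                    out[rname] = {"binmap": binmap, "table": table, "decision": dec}
                thresholded[name] = out

            overlap = {}
            for rname in ("strict", "lenient"):
                overlap[rname] = OverlapReport.build(
                    metric, get_band(band).name,
                    {d.cohort_id: thresholded[d.cohort_id][rname]["binmap"] for d in datasets},
                    pooled_binmap=thresholded["pooled"][rname]["binmap"],
                    connectivity=config.connectivity, affine=affine,
                )

            results["stats"][key] = stats
            results["thresholded"][key] = thresholded
            results["overlap"][key] = overlap
            manifest["analyses"][key] = {
                "residual_fwhm_mm": [float(f) for f in np.atleast_1d(fwhm)],
                "cluster_k": {n: int(v) for n, v in ks.items()},
                "t_hash": {n: _sha(np.nan_to_num(st.t_map)) for n, st in stats.items()},
                "dice_strict": float(overlap["strict"].dice_all),
                "ses_to_t": {
                    n: d_to_t(0.30, st.n_adhd, st.n_tdc) for n, st in stats.items()
                },
            }

            out_dir = os.path.join(config.output_dir, key)
            os.makedirs(out_dir, exist_ok=True)
            for name, st in stats.items():
                thresholded[name]["strict"]["table"].to_csv(
                    os.path.join(out_dir, f"{name}_clusters_strict.tsv"), sep="\t", index=False
                )
            if write_nifti_outputs:
                from .io import write_nifti

                for name, st in stats.items():
                    write_nifti(
                        np.nan_to_num(st.t_map),
                        os.path.join(out_dir, f"{name}_tmap.nii.gz"),
                    )

    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
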