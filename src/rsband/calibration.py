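"""Empirical calibration: injection strength -> realized Cohen's d.

Closed forms for the effect of a coupling or amplitude parameter on ReHo
(Kendall's W) or weighted DC are intractable, so the mapping from each
injection parameter to the standardized group difference it produces is
measured by simulation: two groups are generated that differ only in the
injected effect, each subject is run through the same metric pipeline used
for real analyses, and the per-voxel Cohen's d over the ROI is averaged.

The resulting monotone (param, d) table per effect kind is frozen in
``data/calibration.json`` and inverted by interpolation at generation time.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "realized_effect_d",
    "build_calibration_table",
    "lookup_param",
    "load_table",
]

# conditions used both to build the frozen table and for recovery checks
CAL_GRID = (20, 20, 20)
CAL_N_PER_GROUP = 16
CAL_ROI_RADIUS_MM = 10.0
CAL_BAND = "conventional"


def _roi_center(grid_shape) -> tuple:
    return tuple(int(s) // 2 for s in grid_shape)


def realized_effect_d(
    kind: str,
    param: float,
    seed: int,
    n_per_group: int = CAL_N_PER_GROUP,
    grid_shape=CAL_GRID,
    roi_radius_mm: float = CAL_ROI_RADIUS_MM,
    band: str = CAL_BAND,
) -> float:
    """Measure the Cohen's d an injection parameter produces at the ROI.

    Simulates ``n_per_group`` subjects per group differing only in the
    injected effect, computes the metric the effect targets through the
    standard pipeline, and returns the ROI-mean per-voxel Cohen's d.
    """
    from .groupstats import GroupSample
    from .pipeline import subject_metric_map
    from .simulate import CohortSimSpec, EffectSpec, RoiSphere, simulate_cohort

    metric = {"alff": "ALFF", "reho": "ReHo", "dc_hub": "DC"}[kind]
    roi = RoiSphere(_roi_center(grid_shape), roi_radius_mm)
    spec = CohortSimSpec(
        cohort_id=f"cal-{kind}",
        n_adhd=n_per_group,
        n_tdc=n_per_group,
        grid_shape=tuple(grid_shape),
        effects=[EffectSpec(kind=kind, roi=roi, cohens_d=param, band=band)],
        seed=seed,
    )
    ds = simulate_cohort(spec, calibrated=False)  # cohens_d used as raw param
    roi_m = roi.to_mask(spec.grid_shape, spec.voxel_mm) & ds.brain_mask
    vals = {"ADHD": [], "TDC": []}
    for sub in ds.subjects:
        m = subject_metric_map(sub, metric, band, ds)
        vals[sub.group].append(m.data[roi_m])
    a = np.array(vals["ADHD"])
    t = np.array(vals["TDC"])
    gs = GroupSample(
        mean_adhd=a.mean(axis=0),
        mean_tdc=t.mean(axis=0),
        sd_adhd=a.std(axis=0, ddof=1),
        sd_tdc=t.std(axis=0, ddof=1),
        n_adhd=n_per_group,
        n_tdc=n_per_group,
    )
    return float(np.nanmean(gs.cohens_d()))


DEFAULT_PARAM_GRIDS = {
    "alff": [0.3, 0.5, 0.7, 0.9, 1.2, 1.6],
    "reho": [0.05, 0.1, 0.15, 0.2, 0.3, 0.5],
    "dc_hub": [0.03, 0.06, 0.1, 0.15, 0.25, 0.4],
}


def build_calibration_table(param_grids=None, seeds=(0, 1), **kwargs) -> dict:
    """Measure realized d over a parameter grid, averaged over seeds."""
    param_grids = param_grids or DEFAULT_PARAM_GRIDS
    table = {
        "conditions": {
            "grid_shape": list(kwargs.get("grid_shape", CAL_GRID)),
            "n_per_group": kwargs.get("n_per_group", CAL_N_PER_GROUP),
            "roi_radius_mm": kwargs.get("roi_radius_mm", CAL_ROI_RADIUS_MM),
            "band": kwargs.get("band", CAL_BAND),
            "seeds": list(seeds),
        }
    }
    for kind, params in param_grids.items():
        ds = [
            float(np.mean([realized_effect_d(kind, p, s, **kwargs) for s in seeds]))
            for p in params
        ]
        table[kind] = {"param": [0.0] + list(map(float, params)), "d": [0.0] + ds}
    return table


@lru_cache(maxsize=1)
def load_table() -> dict:
    with resources.files("rsband").joinpath("data/calibration.json").open() as fh:
        return json.load(fh)


def lookup_param(kind: str, cohens_d: float, table: dict | None = None) -> float:
    """Invert the calibration table: target |d| -> injection parameter.

    The (param, d) curve is made monotone by a running maximum before
    interpolation; targets beyond the measured range extrapolate linearly
    along the last segment (clamped to the parameter's valid range for
    coupling-type effects).
    """
    if cohens_d < 0:
        raise ValueError("pass |d|; the sign is carried by group_with_higher_value")
    table = table or load_table()
    if kind not in table:
        raise KeyError(f"no calibration for effect kind {kind!r}")
    params = np.asarray(table[kind]["param"], dtype=float)
    ds = np.maximum.accumulate(np.asarray(table[kind]["d"], dtype=float))
    if cohens_d <= ds[-1]:
        out = float(np.interp(cohens_d, ds, params))
    else:
        slope = (params[-1] - params[-2]) / max(ds[-1] - ds[-2], 1e-9)
        out = float(params[-1] + slope * (cohens_d - ds[-1]))
    if kind in ("reho", "dc_hub"):
        out = min(out, 1.0)
    return out
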