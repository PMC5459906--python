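"""Shared study definition for the numbered analysis scripts.

Four synthetic cohorts mirror the multi-site study design: the group sizes
are the real cohorts' (29/29, 15/15, 28/28, 19/19 ADHD/TDC, all male, TR 2 s,
180 volumes of which 170 are kept), on a 20^3 desk-scale grid at 3 mm. Two
known effects are injected so downstream stages have something to find:

* a shared ALFF increase (ADHD > TDC, d = 0.6) at one central ROI in the
  conventional band — present in every cohort but too weak to reach
  per-cohort significance reliably, the pooled-significant /
  cohort-inconsistent regime;
* cohort-specific ReHo decreases (TDC > ADHD, d = 0.8) at ROIs deliberately
  placed at different locations per cohort — strong but heterogeneous, so
  they never overlap across cohorts.

Note the amplitude injection also *decreases* ReHo at the shared ROI in all
cohorts (independent added signal decorrelates neighbours); the consistency
script points this crosstalk out when it surfaces in the overlap maps.
"""

import os

from rsband.pipeline import StudyConfig

GRID = [20, 20, 20]
SHARED_ALFF_ROI = {"center_vox": [10, 10, 10], "radius_mm": 9.0}

# disjoint per-cohort ReHo ROIs (y/z offsets keep clear of the WM/CSF poles)
_REHO_CENTERS = {
    "nyu": [10, 14, 10],
    "pku1": [10, 6, 10],
    "pku2": [10, 10, 14],
    "pku3": [10, 10, 6],
}
_SIZES = {"nyu": (29, 29), "pku1": (15, 15), "pku2": (28, 28), "pku3": (19, 19)}

RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch")


def study_config(master_seed: int = 7, metrics=("ALFF", "ReHo", "DC")) -> StudyConfig:
    cohorts = []
    for cid, (n_adhd, n_tdc) in _SIZES.items():
        cohorts.append(
            {
                "cohort_id": cid,
                "n_adhd": n_adhd,
                "n_tdc": n_tdc,
                "grid_shape": GRID,
                "effects": [
                    {
                        "kind": "alff",
                        "roi": SHARED_ALFF_ROI,
                        "cohens_d": 0.6,
                        "group_with_higher_value": "ADHD",
                    },
                    {
                        "kind": "reho",
                        "roi": {"center_vox": _REHO_CENTERS[cid], "radius_mm": 8.0},
                        "cohens_d": 0.8,
                        "group_with_higher_value": "TDC",
                    },
                ],
            }
        )
    return StudyConfig(
        cohorts=cohorts,
        bands=["conventional"],
        metrics=list(metrics),
        mc_n_iter=1000,
        output_dir=os.path.join(SCRATCH_DIR, "study"),
        master_seed=master_seed,
    )
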