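"""Compute the three voxel-wise metrics for one cohort across all six bands.

Runs the per-subject pipeline (truncate to 170 volumes, nuisance regression,
band-pass, metric with the correct smoothing order) for the smallest cohort
and tabulates the gray-matter distribution of ALFF, ReHo and DC per band —
showing the expected frequency profile (most BOLD amplitude below 0.1 Hz)
and the ReHo/DC null levels.
"""

import os
import sys
import time

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS_DIR, study_config  # noqa: E402

from rsband.bands import BAND_REGISTRY  # noqa: E402
from rsband.pipeline import subject_metric_map  # noqa: E402
from rsband.simulate import simulate_cohort  # noqa: E402


def main() -> None:
    os.makedirs(RESULTS_DIR, exist_ok=True)
    spec = study_config().cohort_specs()[1]  # pku1: 15+15, the smallest
    ds = simulate_cohort(spec)
    subjects = ds.subjects[:8]
    rows = []
    t0 = time.time()
    for band in BAND_REGISTRY:
        for metric in ("ALFF", "ReHo", "DC"):
            vals = []
            for sub in subjects:
                m = subject_metric_map(sub, metric, band, ds)
                vals.append(np.nanmean(m.data[ds.gm_mask]))
            rows.append(
                {
                    "band": band,
                    "low_hz": BAND_REGISTRY[band].low_hz,
                    "high_hz": BAND_REGISTRY[band].high_hz,
                    "metric": metric,
                    "gm_mean": np.mean(vals),
                    "gm_sd_between_subjects": np.std(vals, ddof=1),
                }
            )
        print(f"band {band} done ({time.time() - t0:.0f}s)")
    table = pd.DataFrame(rows)
    table.to_csv(
        os.path.join(RESULTS_DIR, "metric_band_summary.tsv"),
        sep="\t", index=False, float_format="%.4g",
    )
    print(table.pivot(index="band", columns="metric", values="gm_mean").to_string())
    print(
        "\nReHo sits above its 1/27 independence floor (the baseline noise is "
        "spatially smooth); DC counts suprathreshold (r >= 0.2) correlation mass."
    )


if __name__ == "__main__":
    main()
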