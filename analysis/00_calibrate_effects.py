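"""Calibrate injection strengths against the Cohen's d they realize.

For each effect kind (amplitude/ALFF, local coupling/ReHo, hub coupling/DC)
this measures, by simulation, the standardized group difference the injection
parameter produces at the ROI after the full metric pipeline, and freezes the
monotone (param, d) lookup table the generator uses to hit a requested d.

Writes results/calibration.json and, with --install, updates the packaged
table src/rsband/data/calibration.json.
"""

import argparse
import json
import os
import time

from rsband.calibration import DEFAULT_PARAM_GRIDS, build_calibration_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, nargs="+", default=[0, 1])
    ap.add_argument("--install", action="store_true", help="update the packaged table")
    ap.add_argument("--out", default="results/calibration.json")
    args = ap.parse_args()

    t0 = time.time()
    table = build_calibration_table(seeds=tuple(args.seeds))
    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(table, fh, indent=2)
    print(f"calibration finished in {time.time() - t0:.0f}s -> {args.out}")
    for kind in DEFAULT_PARAM_GRIDS:
        pairs = ", ".join(
            f"{p:g}->{d:.2f}" for p, d in zip(table[kind]["param"], table[kind]["d"])
        )
        print(f"  {kind}: {pairs}")

    if args.install:
        pkg_dir = os.path.join(os.path.dirname(__file__), "..", "src", "rsband", "data")
        os.makedirs(pkg_dir, exist_ok=True)
        dest = os.path.join(pkg_dir, "calibration.json")
        with open(dest, "w") as fh:
            json.dump(table, fh, indent=2)
        print(f"installed -> {dest}")


if __name__ == "__main__":
    main()
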