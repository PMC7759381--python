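#!/usr/bin/env python
"""Capture and inward transport of dynein-coated beads by growing asters.

Renders 20-bead scenes in two regimes (F-actin intact: 0.2 µm/s; F-actin
fragmented: 0.7 µm/s), tracks all particles, gates each bead on its aster
entry time (R(t) crossing) and pools post-entry inward radial speeds.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from asterflux import scenarios

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    report = {}
    rows = []
    for name, speed in (("intact", scenarios.BEAD_SPEED_INTACT),
                        ("fragmented", scenarios.BEAD_SPEED_FRAGMENTED)):
        stack, gt = scenarios.make_bead_regime(seed=args.seed, speed=speed)
        res = scenarios.measure_bead_speed(stack, gt)
        report[name] = {"true_um_s": speed,
                        "mean_um_s": res["mean_inward_speed_um_s"],
                        "sd_um_s": res["sd"], "n_beads": res["n_beads"]}
        for bead_id, v in res["distribution"]["per_bead"].items():
            rows.append({"regime": name, "bead": bead_id,
                         "inward_speed_um_s": v,
                         "entry_time_s": res["entries"].get(bead_id)})
        print(f"{name}: pooled mean {res['mean_inward_speed_um_s']:.3f} "
              f"± {res['sd']:.3f} µm/s over {res['n_beads']} beads "
              f"(true {speed})")
    ratio = report["fragmented"]["mean_um_s"] / report["intact"]["mean_um_s"]
    report["speed_ratio"] = ratio
    print(f"fragmented/intact speed ratio: {ratio:.2f} (~threefold)")
    pd.DataFrame(rows).to_csv(args.outdir / "bead_speeds.csv", index=False)
    with open(args.outdir / "bead_summary.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"wrote {args.outdir/'bead_speeds.csv'} and bead_summary.json")
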