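#!/usr/bin/env python
"""ER enrichment around MTOCs and peripheral depletion, from radial
profiles normalized to the outside-aster mean.

Three regimes: control (2-fold central enrichment), fragmented F-actin
(6-fold, increasing in time) and the peripheral burst regime (30% deficit
in a band just inside the growing periphery).  The aster radius used for
the outside-aster normalization annulus is detected from the MT channel.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from asterflux import scenarios

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for name, fold in (("control_2x", 2.0), ("cytoD_6x", 6.0)):
        stack, gt = scenarios.make_enrichment_scene(seed=args.seed, fold=fold)
        res = scenarios.measure_enrichment(stack, gt)
        prof = res["profile"]
        df = pd.DataFrame(prof.values, index=np.round(prof.t, 1),
                          columns=np.round(prof.bin_centers, 1))
        df.index.name = "t_s"
        df.to_csv(args.outdir / f"radial_profile_{name}.csv")
        tc = res["timecourse"]
        print(f"{name}: final innermost-bin fold = {res['final_fold']:.2f} "
              f"(target {fold}); increasing: {tc['monotone_increasing']}")
    stack, gt = scenarios.make_burst_scene(seed=args.seed, depletion=True)
    dep = scenarios.measure_depletion(stack, gt)
    print(f"burst regime: band deficit {dep['deficit_pct']:.1f}% at "
          f"r = {dep['band_center_um']:.0f} µm (frame {dep['frame']}, "
          f"detected R = {dep['R_detected_um']:.0f} µm; target 30%)")
    print(f"wrote radial_profile_*.csv under {args.outdir}")
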