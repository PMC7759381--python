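#!/usr/bin/env python
"""Oscillating MTOC: tracked speed, MTOC-frame kymograph, and the ratio to
the separation-regime network speed.

Tracks the rendered circular oscillation (25 µm diameter at 1 µm/s), builds
an MTOC-stationary kymograph along the horizontal line through the MTOC,
and compares the tracked speed with the 7 µm/min network speed of a
co-moving separation-regime scene sampled by PIV near the MTOC (the
oscillation is roughly tenfold faster).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from asterflux import scenarios
from asterflux.kymo import line_kymograph

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    stack, gt = scenarios.make_oscillation(seed=args.seed)
    osc = scenarios.measure_oscillation_speed(stack, gt)
    kym = line_kymograph(stack, 0, osc["track"], axis=(1.0, 0.0),
                         reference="mtoc", s_extent=30.0)
    pd.DataFrame(kym.intensity, index=np.round(kym.t, 1),
                 columns=np.round(kym.s, 2)).to_csv(
        args.outdir / "oscillation_kymograph.csv")
    print(f"tracked MTOC speed: {osc['mean_speed_um_s']:.3f} µm/s (true 1.0)")

    stack, gt = scenarios.make_comoving(seed=args.seed)
    net = scenarios.measure_network_speed(stack, gt)
    ratio = osc["mean_speed_um_s"] / net["network_speed_um_s"]
    print(f"separation-regime network speed by PIV: "
          f"{net['network_speed_um_s']*60:.2f} µm/min (true 7)")
    print(f"oscillation / separation speed ratio: {ratio:.1f} "
          "(approximately tenfold)")
    print(f"wrote {args.outdir/'oscillation_kymograph.csv'} "
          "(MTOC-stationary frame: the bright MTOC is a vertical streak "
          "at s = 0)")
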