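#!/usr/bin/env python
"""Mass transport and PIV speeds at the growing aster periphery.

Renders the fragmented-F-actin burst scene (25 µm/min growth, 50 µm inward
band at 0.25 µm/s, organelle flux calibrated to 2% of ROI total per min),
preprocesses it (dark-frame background, flat field, photobleach
normalization), and computes the annular-bin mass-transport map and the
PIV radial-speed map.  The flux map should peak at ~2 %/min along the
diagonal ridge tracking R(t); PIV should read ~0.25 µm/s inward there.
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

    stack, gt = scenarios.make_burst_scene(seed=args.seed)
    flux = scenarios.measure_flux_peak(stack, gt)
    m = flux["map"]
    df = pd.DataFrame(m.flux, index=np.round(m.t, 1),
                      columns=np.round(m.r_edges, 1))
    df.index.name = "t_s"
    df.to_csv(args.outdir / "flux_map.csv")
    band = scenarios.measure_band_speed(stack, gt)
    print(f"true calibrated flux peak: {flux['true_peak']:.2f} %/min")
    print(f"measured flux peak: {flux['peak_flux_pct_per_min']:.2f} %/min "
          f"at r = {flux['r_peak_um']:.0f} µm, t = {flux['t_peak_s']:.0f} s "
          f"(R(t) there: {float(gt.model.R(flux['t_peak_s'])):.0f} µm)")
    print(f"ROI-total conservation after normalization: "
          f"{flux['conservation_rel']:.1e} (relative)")
    print(f"PIV inward band speed: {band['inward_band_speed_um_s']:.3f} µm/s "
          f"(true 0.25) over {band['n_pairs']} frame pairs")
    print(f"wrote {args.outdir/'flux_map.csv'} "
          "(rows: pair time s; cols: radius µm; units % of total per min)")
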