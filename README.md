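# asterflux

Quantitative image analysis of microtubule (MT) aster movement and
cytoplasmic transport in *Xenopus* egg extract: particle image velocimetry
(PIV) of labelled cytoplasmic networks, kymographs in moving reference
frames, Delaunay-based MTOC separation statistics, annular-bin
mass-transport (flux) maps, bead and MTOC tracking, and diffusion analysis
of a photo-released small-molecule cloud — together with a synthetic
time-lapse generator that renders every experimental regime with known
ground truth, so each analysis stage is validated by parameter recovery.

It is written for cell biologists and biophysicists quantifying motion in
fluorescence time-lapse data of cytoplasmic networks (ER, F-actin, MTs,
organelles) around asters, where raw experimental movies are large and
rarely deposited; all results in this repository are computed on synthetic
scenes emulating the published imaging regimes.

## The quantities at the core

- **PIV.** Normalized FFT cross-correlation per 32 px interrogation window
  (50% overlap) with a 3-point Gaussian sub-pixel peak fit and a
  normalized-median outlier test on the 8-neighbourhood; sub-pixel accuracy
  is better than 0.1 px for displacements up to a quarter window.
- **Mass transport.** After background/flat-field correction and
  photobleach normalization, the summed intensity in 10 µm annuli about the
  MTOC is accumulated outward into C(r, t); the net inward flux across
  radius r is F(r, t) = [C(r, t+Δt) − C(r, t)]/Δt, in % of the ROI total
  per minute (positive = toward the MTOC).
- **Cloud diffusometry.** A photo-released fluorescein cloud is fitted per
  frame with a masked isotropic Gaussian I = B + A·exp(−ρ²/2σ²); the width
  obeys σ²(t) = σ₀² + 2D·t, and the apparent cytosol viscosity relative to
  water is D_water/D with D_water = 425 µm²/s.
- **Poroelastic bound.** Advection of sol with a moving gel requires the
  Péclet number Pe = V·L·µ/(E·ξ²) > 1, bounding the network pore size:
  ξ ≤ sqrt(V·L·µ/E).
- **Separation statistics.** MTOC neighbour pairs are the edges of the
  Delaunay triangulation at the first time point; per edge the maximum
  separation speed d′(t) (µm/min) is regressed on the initial distance d₀.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

The numbered drivers under `analysis/` run one scenario each and write
tables under `results/`. For the peripheral-burst transport analysis:

```bash
python analysis/03_mass_transport.py --seed 1
```

prints

```
true calibrated flux peak: 2.00 %/min
measured flux peak: 1.93 %/min at r = 150 µm, t = 335 s (R(t) there: 140 µm)
ROI-total conservation after normalization: 1.9e-16 (relative)
PIV inward band speed: 0.243 µm/s (true 0.25) over 24 frame pairs
```

The scene is a 512² px movie (0.65 µm/px, 10 s frames) of an aster growing
at 25 µm/min whose organelle channel carries a conservative mobile
component calibrated so the true inward flux across the band-centre
circumference peaks at 2% of the ROI total per minute. The measured map
peaks within 0.1 %/min of that calibration on the diagonal ridge tracking
the growing periphery, and PIV on the network channel reads the 0.25 µm/s
inward band speed to within 3%. The other drivers cover the pore-size
bound (`01`, prints ξ ≈ 0.134 µm → ~100 nm), cloud diffusion/viscosity
(`02`, ~6× water), bead transport (`04`, 0.2 vs 0.7 µm/s regimes),
enrichment/depletion profiles (`05`, 2×/6×/−30%), MTOC separation (`06`,
slope ≈ −0.05 (µm/min)/µm) and the oscillation kymograph (`07`, 1 µm/s,
~10× the separation-regime network speed).

A thin CLI wraps the same machinery: `asterflux generate burst --seed 1
--out runs/demo`, `asterflux run --config cfg.yaml`, `asterflux selftest`.

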