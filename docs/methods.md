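# Methods

This note documents the models, parameter choices and numerical decisions
behind `asterflux`. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic scenes and what they emulate

All analyses are validated on synthetic multi-channel time-lapse movies
with exact ground truth. The generator emulates the features of extract
time-lapse data that the analyses are sensitive to:

- **Speckle texture.** Labelled cytoplasmic networks are modelled as
  band-limited Gaussian random fields (white noise smoothed with a 2 px
  Gaussian, configurable contrast). This gives PIV-trackable speckle with
  a correlation length similar to labelled ER/F-actin texture.
- **Advection.** Network channels are advected by the prescribed radial
  flow with per-frame semi-Lagrangian backward warping (bilinear).
  Boundary inflow is filled with fresh texture so the image edge never
  produces spurious static regions.
- **Turnover.** Network turnover is per-frame convex mixing
  I ← (1−α)·warp(I) + α·fresh with α = 1 − exp(−Δt/τ); default τ = 60 s
  (F-actin turnover in extract is about one minute). Organelle channels
  default to no turnover: persistent structures on the movie time scale.
- **Corruption.** A fixed order — advect → bleach (exp(−t/τ_b)) →
  flat-field multiply (radial vignette 1 − s·(r/r_max)²) → background add →
  Gaussian read noise — which the preprocessing pipeline inverts
  (subtract → flat-field divide → photobleach normalize).
- **Mass-carrying components are particles.** Backward warping transports
  *values*, not mass, and is not conservative in a divergent flow, so the
  organelle channel's mobile fraction is rendered as discrete particles
  (Gaussian spots normalized to their exact total intensity) advected
  along the flow by an RK2 integrator. GroundTruth flux is then exact
  bookkeeping of particle crossings.

Features of real data the generator does **not** emulate: saltatory
(run-and-pause) motion of individual organelles, anisotropic or
non-Gaussian PSFs, depth effects and focus drift, structured (non-radial)
illumination fields, camera shot noise (noise is additive Gaussian, per
the error-formula regime), and mechanical deformation of the aster beyond
the prescribed kinematic flow. Passing tests therefore demonstrate that
the estimators recover known kinematics and calibrated fluxes under
realistic noise, bleaching and vignetting — not that they are robust to
every artefact of real microscopy.

## Scene regimes (the study conditions)

Defaults live in `asterflux.scenarios` and are shared by the tests, the
analysis drivers and the acceptance script.

| Scene | Conditions |
|---|---|
| cloud | 512², 0.32 µm/px, 30 frames at 1 s; D = 425/6 µm²/s, σ₀ = 3 µm, peak amplitude A = 10, noise SD µ = 20, bright masked MTOC |
| burst | 512², 0.65 µm/px, 36 frames at 10 s; growth 25 µm/min; 50 µm Tukey band at R(t) moving inward at 0.25 µm/s; organelle flux calibrated to 2 %/min; bleach τ = 600 s, vignette 0.15, background 100 |
| enrichment | as burst but 21 frames at 15 s; central Gaussian accumulation (SD 15 µm) ramping linearly to 2× or 6× the outside-aster mean |
| beads | 256², 60 frames at 10 s; 20 beads at 40–78 µm, jitter SD 0.3 µm; inward speed 0.2 or 0.7 µm/s after R(t) reaches them |
| oscillation | 128², 90 frames at 2 s; MTOC on a 25 µm circle at 1 µm/s |
| co-moving | 256², 30 frames at 10 s; network and MTOC translating at 7 µm/min |
| separation field | 12 MTOC pairs over 600 µm, 10 frames at 60 s; max separation speed = 8 − 0.05·d₀ µm/min, jitter 0.3 µm |

Pixel sizes: 0.65 µm/px for 20×-style scenes (a 300 µm aster fits a 512²
frame), 0.32 µm/px for cloud scenes (the pixel pitch of the published
error-formula regime).

Specific generator decisions:

- **Band shape.** The advection band is a Tukey (cosine-tapered) radial
  window, taper fraction 0.5: flat over the central 25 µm, smooth to zero
  at ±25 µm. The flat top makes "the band speed" well defined for the
  10 µm readout annulus and resolvable by a 32 px PIV window; the taper
  avoids shear discontinuities. The exact profile is recorded in
  GroundTruth.
- **Two textured channels in the burst scene.** A single channel cannot
  simultaneously provide PIV-trackable band motion and a small calibrated
  mass flux: a mostly static texture with a ~15% mobile fraction pins the
  correlation peak at zero displacement. The scene therefore renders a
  fully advected "network" channel (what PIV is run on, as in experiments
  where ER/F-actin speckle is tracked) and an "organelle" channel (static
  texture + calibrated mobile particles) for mass transport.
- **Flux calibration.** The particle weight w solves
  w·peak_rate = τ·(S + w·N) where peak_rate is the maximum per-pair inward
  crossing count of the simulated particles, S the static texture total
  and τ the target flux fraction per minute — so the ground-truth flux
  peak equals the target exactly, including compression/dilution effects
  of the sweeping band.
- **Depletion scene is separate from the flux scene.** A kinematically
  imposed 30% deficit band moving with R(t) would itself transport
  "negative mass" and corrupt the calibrated flux several-fold, so the
  deficit regime (particles off, envelope on) and the flux regime
  (particles on, envelope off) are distinct movies. The deficit band is
  centred at R(t) − 25 µm, just inside the periphery, which also keeps the
  outside-aster normalization annulus (R+10 to R+30 µm) clean.
- **Enrichment calibration.** `central_enrichment` is defined as the
  innermost 10 µm annular-bin readout at the final frame; the Gaussian
  amplitude is divided by the closed-form bin average
  κ = (2s²/b²)(1 − e^(−b²/2s²)) ≈ 0.897 (s = 15 µm, b = 10 µm) so the bin
  value, not the centre pixel, hits the requested fold.
- **Cloud amplitude.** Frames are rendered with constant peak amplitude A.
  A mass-conserving cloud starting at A = 10 with σ₀ = 3 µm would fall to
  A ≈ 0.6 after one second at D ≈ 71 µm²/s and be invisible under noise
  SD 20; constant A is the regime in which per-frame fitting at peak
  SNR ≈ 0.5 is meaningful, which is what the width analysis exercises.
- **Beads park at the MTOC.** Beads are absorbed (no longer rendered) when
  they come within 3 µm of the MTOC, emulating beads joining the bright
  MTOC blob; correspondingly the speed estimator trims post-arrival
  frames (`stop_radius`, default 3–4 µm), since parked beads would dilute
  the pooled speed.
- All stochastic operations take an explicit integer seed; there is no
  global random state, and identical seeds give bit-identical scenes.

## Preprocessing

- Background: per-channel constant. The estimator is the 1st percentile of
  a heavily smoothed (σ = 8 px) first frame — smoothing is essential, as a
  low percentile of the raw frame sits ~2.3 noise SDs below the true
  offset. Fully textured scenes have no signal-free pixels at all, so the
  scenario pipelines instead use a synthetic dark calibration frame (mean
  of read noise about the offset), as one would measure in practice.
- Flat-field: division by a measured calibration frame or a parametric
  vignette, normalized to unit mean (both entry points exist because
  instruments differ in whether the field is measured or modelled).
- Photobleach normalization: each frame scaled so the ROI total (or the
  outside-aster mean, for profile work) equals its first-frame value.
  "Outside the aster" is the annulus R(t)+10 to R(t)+30 µm, clipped to the
  image; the 10 µm inner offset skips the depletion band.

## PIV

Single-pass correlation, 32 px windows, 50% overlap. Numerical points:

- The zero-padded linear correlation sums over (w−|Δy|)(w−|Δx|) terms; this
  tent envelope skews the peak toward zero lag by ≈ σ_corr²/w (≈ 0.25 px
  here). The correlation is divided by the envelope ("unbiased"
  normalization), and the search is restricted to |Δ| ≤ w/4 — the usual
  quarter rule — because the unbiased estimate amplifies spurious
  large-lag peaks. Residual rigid-shift error is < 0.02 px.
- Sub-pixel peak: 3-point Gaussian fit per axis, falling back to a
  parabola when a correlation value is non-positive.
- Outliers: normalized-median test (residual over the 8-neighbourhood
  median residual + ε, threshold 2, ε = 0.1). Flagged vectors are masked,
  never interpolated, and excluded from every downstream statistic.
- Flow fields are only trusted at frame intervals ≤ 20 s (turnover
  destroys inter-frame correlation beyond that); longer intervals warn.
- Line projection uses a corridor of one grid spacing half-width; the
  sign convention is positive toward the second anchor point. The
  neighbourhood radius for sampling velocities near a point defaults to
  15 µm. Radial maps report the signed radial component and the unsigned
  speed separately (they answer different questions; both are computed and
  labelled).

## Tracking and separation statistics

Detection: local maxima of a Gaussian-smoothed frame (σ = 1.5 px) above a
threshold, refined by intensity-weighted centroids in 7×7 windows, with
duplicates within a minimum separation merged. Linking: greedy
mutual-nearest-neighbour per frame pair with a maximum step and no gap
closing — adequate for sparse MTOCs and beads, and it preserves enter/exit
semantics; it is a documented limitation for dense or fast-crossing
particles.

Neighbour pairs are frozen as the Delaunay edges of the MTOC positions at
the earliest time point (scipy's triangulation, validated against a
brute-force empty-circumcircle oracle in the tests). CPC labels (whether
an edge crosses a CPC-positive interaction zone) are *inputs* — a labelled
edge table or a generator rule — never computed from images; labels of 0.5
are treated as CPC-positive. Separation speed per edge: pairwise distance
on common frames, 3-frame centred moving average (minimal smoothing to
stabilize the central differences; no smoothing is otherwise prescribed),
central differences in µm/min, maximum taken over the full common window.
The speed–distance line is fitted by least squares over CPC-positive edges
when at least three exist.

Bead analysis: entry time is the first common frame with
|bead − MTOC| ≤ R(t); post-entry inward speed pools per-frame differences
of the radial distance (positive inward) from entry to arrival.

## Kymographs

Rows are sampled along the line through the MTOC(s) by bilinear
interpolation at 1 px spacing, averaged across a ±2 µm perpendicular
half-width, and translated so the chosen reference (midpoint, MTOC, or
lab) sits at s = 0. With moving MTOCs the line re-orients each frame to
pass through both (a fixed final-frame orientation is available via
`reorient=False`); out-of-image samples are NaN. Relative positions of
annotation tracks are frame-invariant by construction, which the tests
assert.

## Radial profiles and mass transport

Annuli are 10 µm wide and recentred on the MTOC every frame; profile
values are pixel means, transport values pixel *sums* (direct sums avoid
the area bias of mean × ideal-annulus-area where annuli clip the image
edge). Cumulative intensity C(r, t) runs from the centre outward; net
inward flux across r is the inter-frame difference of C divided by the
interval, scaled to % of the ROI total per minute, positive inward.
Because the differences are taken in the MTOC frame on a conserved
(normalized) total, annulus changes sum to zero and the outermost flux
vanishes; a drifting ROI total beyond 1% triggers a warning. Sector
("quadrant") averaging applies an angular mask before binning.

The aster radius R(t) is detected from the MT channel as the largest
radius where the smoothed radial profile crosses the midpoint between the
interior plateau (median of the inner third of bins) and the exterior
plateau (median of the outermost 15%); frames with plateau contrast below
10% yield a missing value, and an isotonic (running-maximum) option
enforces monotone growth.

## Cloud fitting and physical estimates

Per-frame model: isotropic Gaussian with free offset over unmasked pixels
(the bright MTOC is masked by a 3 µm disk so residual bound dye cannot
bias the centre). At peak SNR ≈ 0.5 the SSE landscape has local minima
(narrow Gaussians fitting noise; the offset absorbing a truncated wide
cloud), so initialization is by a width scan: centroid of the smoothed
excess intensity, then a 16-point log-spaced grid over σ with closed-form
(A, B) at each width, polished by bounded trust-region least squares
(A ≥ 0, σ and centre bounded to a neighbourhood of the field). Each frame
is initialized independently — warm starts from a neighbouring frame can
drag the fit into that frame's local minimum. Fits use every second pixel
(the 5-parameter fit is over-determined by ~10⁴×; stride 2 quarters the
cost). Standard errors come from the residual-scaled Gauss–Newton
covariance.

The diffusion fit is a weighted straight line through σ²(t), weights
1/var(σ²) propagated from the per-frame standard errors. The release
frame itself is excluded: at t = t_release the σ₀ = 3 µm cloud is still
mostly hidden behind the 3 µm MTOC mask and its width estimate is badly
conditioned. Viscosity relative to water is D_water/D with
D_water = 425 µm²/s (fluorescein), overridable.

Localization error: two candidate formulas are implemented and labelled.
The adopted form, err = sqrt(2/π)·(h·µ/A) (in µm; /h for px), is the exact
Fisher-information result for an isotropic-Gaussian centre fit with peak
amplitude A, noise SD µ and pixel pitch h — notably independent of σ. At
h = 0.32 µm, µ = 20, A = 10 it gives 0.51 µm = 1.6 px, i.e. on the order
of a pixel. The literal algebraic reading (2/π)·(h·µ/A)² = 0.26 is kept
behind `form="printed"`; Monte-Carlo localization SDs in the tests fall
between the two candidates' brackets. The two forms are never mixed.

Drift correction is ordinary least squares for a constant velocity u
minimizing Σ‖c(t) − u·(t−t₀) − m(t)‖² (closed form, exact in the noiseless
case); registration RMS before/after is reported. Only constant drift is
modelled — no spatially varying flow inference from the cloud, and no
hypothesis test on the drift's origin (the error-formula comparison is
reported instead).

Poroelastic algebra: Pe = V·L·µ/(E·ξ²) and ξ = sqrt(V·L·µ/(E·Pe)) with SI
units internally; the bound is reported in µm and nm, and additionally
rounded to one significant figure, as such order-of-magnitude bounds are
quoted. Defaults V = 1 µm/s, L = 30 µm (the oscillation regime),
µ = 6 × water, E = 10 Pa.

## Problem sizes

Scenes are at most 512² px and ≤ 90 frames; the recovery suite uses one
seed per scenario except the viscosity check (50 seeds, per-seed tolerance
15%, mean bias 5%). These sizes put every estimator comfortably in its
asymptotic regime (e.g. ≥ 400 particle crossings at the flux peak, ~86 PIV
vectors per annulus at the band) while keeping the full suite and the
acceptance script in the minutes range on one core.

## Known limitations

- Single-pass PIV (no multi-grid window deformation, no ensemble
  correlation, no optical flow): displacements must stay below w/4 per
  frame and strong within-window shear biases vectors toward the locally
  dominant texture.
- Greedy mutual-NN linking can swap identities of beads converging near
  the MTOC; pooled speed statistics are insensitive to such swaps, but
  individual tracks near the centre should not be over-interpreted.
- The kinematic depletion envelope and the calibrated advective flux are
  mutually exclusive within one channel (see above); real data of course
  has both at once, generated self-consistently by the same transport.
- Flux maps do not separate diffusive from advective contributions, and
  all geometry is 2-D (no shells, no 3-D stacks).
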