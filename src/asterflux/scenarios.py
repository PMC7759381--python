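"""Canonical study conditions: scene builders and end-to-end measurements.

Each ``make_*`` function fixes the imaging conditions and kinematic regime
of one experimental scenario (cloud photo-release, peripheral burst
transport, ER enrichment, bead capture, MTOC oscillation and separation);
each ``measure_*`` function runs the corresponding analysis pipeline on the
rendered movie and returns the headline numbers.  The acceptance script,
the analysis drivers and the CLI all import these so every entry point
computes the same quantities under the same conditions.

Background calibration: textured scenes have no signal-free pixels, so the
scenario pipelines estimate the camera offset from a synthetic dark frame
(mean of read noise around the offset), as one would from a dark
calibration acquisition; sparse scenes use the smoothed-percentile
estimator.
"""

from __future__ import annotations

import math

import numpy as np

from . import cloud as cloudmod
from . import imgprep, piv, radial, tracking
from .core import ImageStack, Trajectory
from .synthio import (AsterModel, ChannelSpec, CloudModel, GroundTruth,
                      SceneParams, make_aster_scene, make_bead_scene,
                      make_cloud_sequence, make_comoving_scene,
                      make_mtoc_field, make_oscillation_scene)

# ---------------------------------------------------------------------------
# poroelastic bound (closed form; the oscillation regime's parameters)
# ---------------------------------------------------------------------------

POROELASTIC = {"V": 1e-6,          # m/s   (~1 µm/s oscillation speed)
               "L": 30e-6,         # m     (~30 µm oscillation amplitude)
               "mu": 6 * 1.0e-3,   # Pa s  (cytosol ~6x water)
               "E": 10.0}          # Pa    (aster gel elastic modulus)


def target_pore_size() -> dict[str, float]:
    return cloudmod.pore_size_bound(**POROELASTIC)


# ---------------------------------------------------------------------------
# cloud photo-release / viscosity
# ---------------------------------------------------------------------------


def make_cloud_scene(seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """30 frames at 1 s, 0.32 µm/px, cloud D = 425/6 µm²/s, A = 10,
    noise SD 20 — the published fitting regime."""
    params = SceneParams(image_shape=(512, 512), pixel_size=0.32,
                         frame_interval=1.0, n_frames=30,
                         bleach_tau=math.inf, flatfield_strength=0.0,
                         noise_sd=20.0, background_offset=10.0, seed=seed)
    model = CloudModel(release_time=0.0, D=425.0 / 6.0, sigma0=3.0,
                       amplitude=10.0, mtoc_amplitude=200.0,
                       mtoc_mask_radius=3.0)
    return make_cloud_sequence(params, model)


def measure_viscosity(stack: ImageStack, gt: GroundTruth) -> dict:
    # the release frame itself is skipped: at t = t_release the cloud
    # (sigma0 = 3 µm) is still mostly hidden behind the 3 µm MTOC mask and
    # its width estimate is strongly biased
    release_frame = int(np.searchsorted(stack.times,
                                        gt.cloud.release_time) + 1)
    fits = cloudmod.fit_cloud_series(stack, 0, gt.mtoc,
                                     mask_radius=gt.cloud.mtoc_mask_radius,
                                     release_frame=release_frame)
    dfit = cloudmod.fit_diffusion(fits, release_time=gt.cloud.release_time)
    return {"D": dfit.D, "viscosity_ratio": dfit.viscosity_ratio,
            "sigma0_sq": dfit.sigma0_sq, "fits": fits}


# ---------------------------------------------------------------------------
# peripheral-burst aster scenes (flux, PIV band speed, depletion)
# ---------------------------------------------------------------------------

BURST_BAND_SPEED = 0.25     # µm/s inward, fragmented-F-actin regime
BURST_TARGET_FLUX = 2.0     # % of ROI total per min at the band peak
BURST_DEPLETION = 0.30      # fractional deficit in the peripheral band


def make_burst_scene(seed: int = 0, depletion: bool = False,
                     ) -> tuple[ImageStack, GroundTruth]:
    """Growing aster (25 µm/min) with a 50 µm inward advection band.

    ``depletion=False``: the organelle channel carries a conservative
    particle component calibrated so the true inward flux peaks at
    2 % of the ROI total per minute (the mass-transport scenario).
    ``depletion=True``: the particle component is off and a 30% Tukey
    deficit rides just inside the periphery (the profile-deficit scenario;
    a kinematically imposed deficit would corrupt a flux calibration, so
    the two regimes are separate movies).
    """
    params = SceneParams(image_shape=(512, 512), pixel_size=0.65,
                         frame_interval=10.0, n_frames=36, bleach_tau=600.0,
                         flatfield_strength=0.15, noise_sd=20.0,
                         background_offset=100.0, texture_turnover_tau=60.0,
                         seed=seed)
    model = AsterModel(growth_rate=25.0, v_peripheral=-BURST_BAND_SPEED,
                       band_width=50.0, band_taper=0.5,
                       peripheral_depletion=BURST_DEPLETION if depletion
                       else 0.0)
    channels = [
        ChannelSpec("organelle", texture_mean=2000.0, texture_contrast=0.10,
                    advected=False, turnover_tau=math.inf,
                    n_particles=0 if depletion else 20000,
                    target_peak_flux=None if depletion else BURST_TARGET_FLUX,
                    apply_depletion=depletion),
        ChannelSpec("network", texture_mean=2000.0, texture_contrast=0.25,
                    advected=True, turnover_tau=60.0),
        ChannelSpec("mt", texture_mean=1500.0, texture_contrast=0.08,
                    advected=False, turnover_tau=math.inf, interior_step=0.6),
    ]
    return make_aster_scene(params, model, channels)


def _dark_frame_offset(params: SceneParams) -> float:
    """Camera offset from a synthetic dark calibration frame."""
    rng = np.random.default_rng(params.seed + 986_513)
    dark = params.background_offset + rng.normal(0, params.noise_sd,
                                                 params.image_shape)
    return float(dark.mean())


def preprocess_transport(stack: ImageStack, gt: GroundTruth) -> ImageStack:
    """Background (dark frame) -> flat-field -> ROI-total bleach norm."""
    prepped, _ = imgprep.preprocess(
        stack, flatfield=gt.flatfield, background="constant",
        background_value=_dark_frame_offset(gt.params),
        bleach_mode="roi_total", channel="organelle")
    return prepped


def measure_flux_peak(stack: ImageStack, gt: GroundTruth) -> dict:
    prepped = preprocess_transport(stack, gt)
    mmap = radial.mass_transport_map(prepped, "organelle", gt.mtoc,
                                     bin_width=10.0)
    peak, r_pk, t_pk = mmap.peak()
    true_peak = float(np.nanmax(gt.flux_map.flux))
    # conservation: inter-frame changes sum to zero over all annuli
    sums = np.empty(prepped.n_frames)
    for k in range(prepped.n_frames):
        sums[k] = prepped.channel("organelle")[k].sum()
    conservation = float(np.abs(np.diff(sums)).max() / sums.mean())
    return {"peak_flux_pct_per_min": float(peak), "r_peak_um": r_pk,
            "t_peak_s": t_pk, "true_peak": true_peak, "map": mmap,
            "conservation_rel": conservation}


def measure_band_speed(stack: ImageStack, gt: GroundTruth,
                       window_size: int = 32, overlap: float = 0.5) -> dict:
    """Mean signed radial PIV velocity in the band-centre annulus."""
    fields = piv.compute_flow(stack, "network", window_size, overlap)
    fields = [piv.filter_outliers(f) for f in fields]
    rmap = piv.radial_speed_map(fields, gt.mtoc, bin_width=10.0)
    half = min(stack.shape) * stack.pixel_size / 2
    vals = []
    for k, f in enumerate(fields):
        R = float(gt.model.R(f.t))
        if not (40.0 <= R <= half - 25.0):
            continue    # band not yet developed / partially off-image
        j = int(np.argmin(np.abs(rmap["r_centers"] - R)))
        v = rmap["radial"][k, j]
        if np.isfinite(v):
            vals.append(v)
    inward = -float(np.mean(vals))
    return {"inward_band_speed_um_s": inward, "n_pairs": len(vals),
            "fields": fields}


def measure_depletion(stack: ImageStack, gt: GroundTruth,
                      target_R: float = 100.0) -> dict:
    """Band-bin deficit (%) of the outside-normalized profile at the frame
    where the periphery is nearest ``target_R``."""
    prepped, _ = imgprep.preprocess(
        stack, flatfield=gt.flatfield, background="constant",
        background_value=_dark_frame_offset(gt.params), bleach_mode=None)
    Rdet = radial.detect_aster_radius(prepped, "mt", gt.mtoc, monotone=True)
    prof = radial.radial_profile(prepped, "organelle", gt.mtoc,
                                 bin_width=10.0, normalize_outside=True,
                                 R=Rdet)
    frame = int(np.argmin(np.abs(np.asarray(gt.model.R(stack.times))
                                 - target_R)))
    center = gt.depletion_center(stack.times[frame])
    val = radial.band_bin_value(prof, center, frame)
    return {"deficit_pct": 100.0 * (1.0 - val), "band_value": val,
            "frame": frame, "band_center_um": center,
            "R_detected_um": float(Rdet(stack.times[frame]))}


# ---------------------------------------------------------------------------
# ER central enrichment scenes
# ---------------------------------------------------------------------------


def make_enrichment_scene(seed: int = 0, fold: float = 2.0,
                          ) -> tuple[ImageStack, GroundTruth]:
    """Growing aster with a central Gaussian ER accumulation ramping
    linearly to ``fold`` times the outside-aster mean at the final frame."""
    params = SceneParams(image_shape=(512, 512), pixel_size=0.65,
                         frame_interval=15.0, n_frames=21, bleach_tau=600.0,
                         flatfield_strength=0.15, noise_sd=20.0,
                         background_offset=100.0, seed=seed)
    model = AsterModel(growth_rate=25.0, central_enrichment=fold,
                       enrichment_sigma=15.0)
    channels = [
        ChannelSpec("organelle", texture_mean=2000.0, texture_contrast=0.10,
                    advected=False, turnover_tau=math.inf,
                    apply_enrichment=True),
        ChannelSpec("mt", texture_mean=1500.0, texture_contrast=0.08,
                    advected=False, turnover_tau=math.inf, interior_step=0.6),
    ]
    return make_aster_scene(params, model, channels)


def measure_enrichment(stack: ImageStack, gt: GroundTruth) -> dict:
    prepped, _ = imgprep.preprocess(
        stack, flatfield=gt.flatfield, background="constant",
        background_value=_dark_frame_offset(gt.params), bleach_mode=None)
    Rdet = radial.detect_aster_radius(prepped, "mt", gt.mtoc, monotone=True)
    prof = radial.radial_profile(prepped, "organelle", gt.mtoc,
                                 bin_width=10.0, normalize_outside=True,
                                 R=Rdet)
    tc = radial.enrichment_timecourse(prof, inner_radius=10.0)
    return {"final_fold": tc["final"], "timecourse": tc, "profile": prof,
            "R_detected": Rdet}


# ---------------------------------------------------------------------------
# bead capture-and-transport scenes
# ---------------------------------------------------------------------------

BEAD_SPEED_INTACT = 0.2      # µm/s, F-actin intact
BEAD_SPEED_FRAGMENTED = 0.7  # µm/s, F-actin fragmented


def make_bead_regime(seed: int = 0, speed: float = BEAD_SPEED_INTACT,
                     n_beads: int = 20) -> tuple[ImageStack, GroundTruth]:
    params = SceneParams(image_shape=(256, 256), pixel_size=0.65,
                         frame_interval=10.0, n_frames=60, bleach_tau=1200.0,
                         flatfield_strength=0.10, noise_sd=20.0,
                         background_offset=100.0, seed=seed)
    model = AsterModel(growth_rate=25.0)
    return make_bead_scene(params, model, bead_speed_inside=speed,
                           n_beads=n_beads, bead_radii=(40.0, 78.0),
                           jitter_sd=0.3)


def _split_mtoc_and_beads(trajs: list[Trajectory], stack: ImageStack,
                          center: tuple[float, float]):
    """The MTOC is the long, nearly static trajectory at the aster centre."""
    best = None
    for tr in trajs:
        if len(tr) < 0.9 * stack.n_frames:
            continue
        disp = float(np.hypot(tr.x - tr.x.mean(), tr.y - tr.y.mean()).max())
        d_ctr = math.hypot(tr.x.mean() - center[0], tr.y.mean() - center[1])
        if disp < 5.0 and (best is None or d_ctr < best[0]):
            best = (d_ctr, tr)
    if best is None:
        raise ValueError("no static central trajectory found for the MTOC")
    mtoc = best[1]
    beads = [tr for tr in trajs if tr.id != mtoc.id and len(tr) >= 5]
    return mtoc, beads


def measure_bead_speed(stack: ImageStack, gt: GroundTruth) -> dict:
    """Full tracking pipeline: detect, link, gate on aster entry, pool
    post-entry inward radial speeds."""
    trajs = tracking.track_stack(stack, 0, min_intensity=350.0, min_sep=4.0,
                                 max_step=11.0)
    mtoc, beads = _split_mtoc_and_beads(trajs, stack,
                                        gt.params.center_um)
    R = gt.aster_radius
    entries = {}
    for b in beads:
        te = tracking.aster_entry_time(b, mtoc, R)
        if te is not None:
            entries[b.id] = te
    dist = tracking.bead_velocity_distribution(beads, mtoc, entries,
                                               stop_radius=4.0)
    return {"mean_inward_speed_um_s": dist["mean"], "sd": dist["sd"],
            "n_beads": len(dist["per_bead"]), "entries": entries,
            "distribution": dist}


# ---------------------------------------------------------------------------
# MTOC oscillation and co-moving network scenes
# ---------------------------------------------------------------------------

OSCILLATION_SPEED = 1.0      # µm/s on a 25 µm diameter circle
SEPARATION_NETWORK_SPEED = 7.0 / 60.0   # µm/s (7 µm/min separation regime)


def make_oscillation(seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    params = SceneParams(image_shape=(128, 128), pixel_size=0.65,
                         frame_interval=2.0, n_frames=90,
                         bleach_tau=math.inf, flatfield_strength=0.0,
                         noise_sd=20.0, background_offset=100.0, seed=seed)
    return make_oscillation_scene(params, diameter=25.0,
                                  speed=OSCILLATION_SPEED)


def measure_oscillation_speed(stack: ImageStack, gt: GroundTruth) -> dict:
    trajs = tracking.track_stack(stack, 0, min_intensity=500.0, min_sep=5.0,
                                 max_step=5.0)
    traj = max(trajs, key=len)
    if len(traj) < 0.9 * stack.n_frames:
        raise ValueError("MTOC track fragmented")
    return {"mean_speed_um_s": tracking.mean_speed(traj), "track": traj}


def make_comoving(seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    params = SceneParams(image_shape=(256, 256), pixel_size=0.65,
                         frame_interval=10.0, n_frames=30,
                         bleach_tau=math.inf, flatfield_strength=0.0,
                         noise_sd=20.0, background_offset=100.0,
                         texture_turnover_tau=60.0, seed=seed)
    return make_comoving_scene(params,
                               velocity=(SEPARATION_NETWORK_SPEED, 0.0))


def measure_network_speed(stack: ImageStack, gt: GroundTruth) -> dict:
    """PIV network speed sampled in the neighbourhood of the moving MTOC."""
    fields = piv.compute_flow(stack, "network", 32, 0.5)
    fields = [piv.filter_outliers(f) for f in fields]
    t, sp = piv.sample_near_point(fields, gt.mtoc, radius=15.0)
    return {"network_speed_um_s": float(np.nanmean(sp)), "t": t, "speeds": sp}


# ---------------------------------------------------------------------------
# MTOC separation field (trajectory tables)
# ---------------------------------------------------------------------------

SEPARATION_SLOPE = -0.05     # (µm/min)/µm
SEPARATION_INTERCEPT = 8.0   # µm/min


def make_separation_field(seed: int = 0, n_mtocs: int = 24,
                          jitter_sd: float = 0.3):
    return make_mtoc_field(n_mtocs, domain=(600.0, 600.0),
                           speed_model=(SEPARATION_SLOPE,
                                        SEPARATION_INTERCEPT),
                           d0_range=(40.0, 120.0), n_frames=10,
                           frame_interval=60.0, jitter_sd=jitter_sd,
                           seed=seed)


def measure_separation_fit(trajs, labels) -> dict:
    graph = tracking.build_neighbor_graph(trajs, labels)
    table, fit = tracking.separation_analysis(graph, trajs)
    return {"table": table, "fit": fit}
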