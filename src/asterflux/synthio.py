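"""Synthetic fluorescence time-lapse generator with exact ground truth.

Every analysis stage in this package is validated by parameter recovery on
scenes from this module: growing radial asters whose textured network and
organelle channels are advected by prescribed flow fields, bright MTOC/bead
particles on known trajectories, and a photo-released diffusing Gaussian
cloud.  Image corruption follows a fixed order that preprocessing inverts:

    advect -> bleach -> flat-field multiply -> background add -> read noise

Textures are band-limited Gaussian random fields (white noise smoothed with
a 2 px Gaussian), which gives PIV-trackable speckle similar to labelled
cytoplasmic networks.  Network turnover is modelled as per-frame convex
mixing with fresh texture at rate 1/turnover_tau (the F-actin turnover time
scale in extract is about one minute).

Mass-carrying components are rendered as discrete particles advected along
the analytic flow, because semi-Lagrangian warping of a texture transports
*values*, not mass, and is therefore not conservative in a divergent flow.
Particles conserve intensity exactly, so the GroundTruth flux is exact
bookkeeping of particle crossings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .core import AsterRadiusTable, ImageStack, Trajectory

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Imaging conditions shared by all scene types.

    ``noise_sd`` is the Gaussian read-noise standard deviation (the µ of the
    Gaussian-fit positional-error formula); ``texture_turnover_tau`` the
    default network turnover time constant in seconds (~60 s for F-actin).
    ``bleach_tau`` of ``inf`` disables photobleaching.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65          # µm/px (20x-style default)
    frame_interval: float = 10.0      # s; PIV wants <= 20 s
    n_frames: int = 40
    bleach_tau: float = math.inf      # s
    flatfield_strength: float = 0.0   # 0 = uniform illumination
    noise_sd: float = 20.0            # intensity units
    background_offset: float = 100.0  # intensity units
    texture_turnover_tau: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture_turnover_tau <= 0:
            raise ValueError("texture_turnover_tau must be > 0")
        for name in ("bleach_tau", "flatfield_strength", "background_offset"):
            if not np.isfinite(getattr(self, name)) and name != "bleach_tau":
                raise ValueError(f"{name} must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def extent_um(self) -> tuple[float, float]:
        ny, nx = self.image_shape
        return ny * self.pixel_size, nx * self.pixel_size

    @property
    def center_um(self) -> tuple[float, float]:
        ny, nx = self.image_shape
        return (nx - 1) / 2 * self.pixel_size, (ny - 1) / 2 * self.pixel_size


@dataclass
class AsterModel:
    """Kinematics and intensity regime of a growing radial aster.

    The periphery radius is R(t) = r0 + growth_rate/60 * t (µm, clipped to
    the image).  The radial texture velocity is ``v_interior`` inside the
    aster plus ``v_peripheral`` within a cosine-tapered (Tukey) band of width
    ``band_width`` centred on R(t); negative values point inward.

    ``central_enrichment`` is the target fold-ratio of the innermost
    ``enrichment_ref_radius`` annular bin to the outside-aster mean at the
    final frame (a Gaussian accumulation of SD ``enrichment_sigma`` ramping
    linearly in time; the analytic bin-average factor is applied so the
    *bin readout* hits the requested fold).  ``peripheral_depletion`` is the
    fractional intensity deficit of a Tukey band centred just inside the
    periphery, at R(t) - band_width/2.
    """

    growth_rate: float = 25.0         # µm/min
    r0: float = 0.0                   # µm
    v_interior: float = 0.0           # µm/s, signed radial (+ = outward)
    v_peripheral: float = 0.0         # µm/s, signed radial (- = inward burst)
    band_width: float = 50.0          # µm
    band_taper: float = 0.5           # Tukey taper fraction
    central_enrichment: float = 1.0   # fold
    enrichment_sigma: float = 15.0    # µm
    enrichment_ref_radius: float = 10.0  # µm (readout bin width)
    peripheral_depletion: float = 0.0    # fraction in [0, 1)
    mtoc_xy: tuple[float, float] | None = None  # µm; None = image centre
    mtoc_trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.band_width <= 0:
            raise ValueError("band_width must be > 0")
        if self.central_enrichment < 1:
            raise ValueError("central_enrichment must be >= 1 "
                             "(use peripheral_depletion for deficits)")
        if not 0 <= self.peripheral_depletion < 1:
            raise ValueError("peripheral_depletion must be in [0, 1)")

    def R(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.r0 + self.growth_rate / 60.0 * np.asarray(t, dtype=float)


@dataclass
class ChannelSpec:
    """What one fluorescence channel of an aster scene contains."""

    name: str
    texture_mean: float = 2000.0
    texture_contrast: float = 0.25    # texture SD / mean
    advected: bool = False            # warp texture by the aster flow
    turnover_tau: float | None = None  # None -> SceneParams default; inf = off
    n_particles: int = 0              # conservative mobile component
    particle_weight: float | None = None  # total intensity per particle
    target_peak_flux: float | None = None  # %/min; calibrates particle_weight
    particle_sigma: float = 1.0       # µm, rendered spot SD
    apply_enrichment: bool = False
    apply_depletion: bool = False
    interior_step: float = 0.0        # fold elevation inside R(t) (MT channel)


@dataclass
class CloudModel:
    """Photo-released diffusing Gaussian cloud riding a bright MTOC.

    The rendered cloud is a circular Gaussian with per-axis variance
    sigma(t)^2 = sigma0^2 + 2 D (t - release_time), centred at
    ``release_position + drift_velocity * (t - release_time)`` and rendered
    with constant peak amplitude ``amplitude`` (the per-frame fitting regime;
    see methods note).  Frames before release contain only background and
    the MTOC spot.
    """

    release_time: float = 0.0
    release_position: tuple[float, float] | None = None  # µm; None = MTOC
    D: float = 70.8                   # µm²/s
    sigma0: float = 3.0               # µm
    amplitude: float = 10.0           # intensity units (A)
    mtoc_amplitude: float = 200.0
    mtoc_sigma: float = 0.6           # µm
    mtoc_mask_radius: float = 3.0     # µm
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # µm/s

    def __post_init__(self) -> None:
        if self.D <= 0 or self.sigma0 <= 0 or self.amplitude <= 0:
            raise ValueError("D, sigma0 and amplitude must be > 0")

    def sigma_sq(self, t: np.ndarray | float) -> np.ndarray | float:
        dt = np.maximum(np.asarray(t, dtype=float) - self.release_time, 0.0)
        return self.sigma0 ** 2 + 2.0 * self.D * dt


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene.

    ``velocity_profile(r, t)`` gives the signed radial texture velocity in
    µm/s; ``flow_field(frame)`` the exact per-pixel (u, v) at that frame's
    time.  For channels with a particle component, ``flux_map`` holds the
    exact inward particle-intensity crossings per 10 µm radius per frame
    pair in % of total channel intensity per minute, and ``analytic_flux``
    the corresponding rho*v*2*pi*r prediction for the initial density.
    """

    params: SceneParams
    model: AsterModel | None = None
    cloud: CloudModel | None = None
    mtoc: Trajectory | None = None
    trajectories: list[Trajectory] = field(default_factory=list)
    aster_radius: AsterRadiusTable | None = None
    velocity_profile: Callable | None = None
    flatfield: np.ndarray | None = None
    bleach_factors: np.ndarray | None = None
    particle_radii: np.ndarray | None = None   # (n_frames, n_particles) µm
    particle_weight: float | None = None
    static_total: float | None = None
    flux_map: "object | None" = None           # core.MassTransportMap
    analytic_flux: "object | None" = None
    sigma_sq: np.ndarray | None = None         # cloud per-frame variance
    cloud_centers: np.ndarray | None = None    # (n_frames, 2) µm
    entry_times: dict[int, float] = field(default_factory=dict)
    depletion_center: Callable | None = None   # t -> µm
    extras: dict = field(default_factory=dict)

    def flow_field(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Exact (u, v) in µm/s at every pixel centre for ``frame``."""
        if self.velocity_profile is None or self.mtoc is None:
            raise ValueError("scene has no flow field")
        t = self.params.times[frame]
        cx, cy = self.mtoc.interp(t)
        rr, xx, yy = _radius_grid(self.params, cx, cy)
        vr = self.velocity_profile(rr, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            ex = np.where(rr > 0, (xx - cx) / rr, 0.0)
            ey = np.where(rr > 0, (yy - cy) / rr, 0.0)
        return vr * ex, vr * ey


# ---------------------------------------------------------------------------
# low-level rendering primitives
# ---------------------------------------------------------------------------


def bandlimited_texture(rng: np.random.Generator, shape: tuple[int, int],
                        mean: float, contrast: float,
                        corr_sigma_px: float = 2.0) -> np.ndarray:
    """Band-limited Gaussian random field with given mean and contrast."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_sigma_px)
    sd = f.std()
    if sd > 0:
        f /= sd
    return np.clip(mean * (1.0 + contrast * f), 0.0, None)


def render_spots(shape: tuple[int, int], pixel_size: float,
                 x_um: np.ndarray, y_um: np.ndarray,
                 amplitude: np.ndarray | float, sigma_um: float,
                 normalize: str = "peak") -> np.ndarray:
    """Render Gaussian spots by vectorised stamping.

    ``normalize='peak'`` makes ``amplitude`` the peak intensity;
    ``'sum'`` makes it the total (integrated) intensity of the spot.
    """
    ny, nx = shape
    img = np.zeros(ny * nx)
    x_px = np.atleast_1d(np.asarray(x_um, dtype=float)) / pixel_size
    y_px = np.atleast_1d(np.asarray(y_um, dtype=float)) / pixel_size
    n = len(x_px)
    if n == 0:
        return img.reshape(shape)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (n,)).copy()
    s = sigma_um / pixel_size
    rad = max(3, int(math.ceil(4.0 * s)))
    off = np.arange(-rad, rad + 1)
    gx = np.round(x_px).astype(int)[:, None] + off[None, :]   # (n, k)
    gy = np.round(y_px).astype(int)[:, None] + off[None, :]
    wx = np.exp(-((gx - x_px[:, None]) ** 2) / (2 * s * s))
    wy = np.exp(-((gy - y_px[:, None]) ** 2) / (2 * s * s))
    if normalize == "sum":
        # normalize by the discrete kernel sum so each spot carries exactly
        # its stated total intensity (conservative rendering)
        amp = amp / (wx.sum(axis=1) * wy.sum(axis=1))
    patch = amp[:, None, None] * wy[:, :, None] * wx[:, None, :]
    iy = np.broadcast_to(gy[:, :, None], patch.shape)
    ix = np.broadcast_to(gx[:, None, :], patch.shape)
    ok = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    flat = (iy[ok] * nx + ix[ok])
    img = np.bincount(flat, weights=patch[ok], minlength=ny * nx)
    return img.reshape(shape)


def warp_backward(img: np.ndarray, u_px: np.ndarray, v_px: np.ndarray,
                  fill: np.ndarray | None = None) -> np.ndarray:
    """Semi-Lagrangian backward warp by one frame.

    ``u_px, v_px`` are the per-pixel displacement (in pixels) of the pattern
    over the frame interval, evaluated at the destination.  Source samples
    falling outside the image are replaced by ``fill`` (fresh texture) so
    boundary inflow does not produce spurious dark or static regions.
    """
    ny, nx = img.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    src = np.array([rows - v_px, cols - u_px])
    out = ndimage.map_coordinates(img, src, order=1, mode="constant",
                                  cval=np.nan)
    bad = ~np.isfinite(out)
    if bad.any():
        if fill is None:
            out2 = ndimage.map_coordinates(img, src, order=1, mode="nearest")
            out[bad] = out2[bad]
        else:
            out[bad] = fill[bad]
    return out


def tukey_band(r: np.ndarray, center: float, width: float,
               taper: float = 0.5) -> np.ndarray:
    """Tukey (cosine-tapered) radial band: 1 on the flat top, 0 outside."""
    hw = width / 2.0
    x = np.abs(np.asarray(r, dtype=float) - center)
    flat = hw * (1.0 - taper)
    out = np.zeros_like(x)
    out[x <= flat] = 1.0
    ramp = hw - flat
    if ramp > 0:
        sel = (x > flat) & (x < hw)
        out[sel] = np.cos(0.5 * math.pi * (x[sel] - flat) / ramp) ** 2
    return out


def _radius_grid(params: SceneParams, cx: float, cy: float):
    ny, nx = params.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    xx *= params.pixel_size
    yy *= params.pixel_size
    rr = np.hypot(xx - cx, yy - cy)
    return rr, xx, yy


def parametric_vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial polynomial vignette 1 - strength * (r / r_max)^2."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    return 1.0 - strength * r2 / r2.max()


def corrupt_stack(clean: np.ndarray, params: SceneParams,
                  rng: np.random.Generator):
    """Apply bleach -> flat-field -> background -> noise, in that order.

    Returns the corrupted stack, the bleach factors and the flat-field
    image, so ground truth can be propagated.
    """
    t = params.times
    bleach = (np.exp(-t / params.bleach_tau) if np.isfinite(params.bleach_tau)
              else np.ones_like(t))
    ff = parametric_vignette(clean.shape[-2:], params.flatfield_strength)
    out = clean * bleach[(...,) + (None,) * (clean.ndim - 1)]
    out = out * ff
    out = out + params.background_offset
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return out, bleach, ff


# ---------------------------------------------------------------------------
# aster scenes
# ---------------------------------------------------------------------------


def _mtoc_trajectory(params: SceneParams, model: AsterModel) -> Trajectory:
    if model.mtoc_trajectory is not None:
        return model.mtoc_trajectory
    cx, cy = model.mtoc_xy if model.mtoc_xy is not None else params.center_um
    t = params.times
    return Trajectory(0, np.arange(params.n_frames), t,
                      np.full_like(t, cx), np.full_like(t, cy), label="mtoc")


def _radial_velocity_profile(model: AsterModel):
    """Signed radial texture velocity v_r(r, t) in µm/s."""

    def vr(r, t):
        r = np.asarray(r, dtype=float)
        R = float(np.asarray(model.R(t)))
        band = tukey_band(r, R, model.band_width, model.band_taper)
        v = model.v_peripheral * band
        if model.v_interior != 0.0:
            hw = model.band_width / 2.0
            interior = 1.0 / (1.0 + np.exp((r - (R - hw)) / 2.0))
            v = v + model.v_interior * interior
        return v

    return vr


def _advect_radii(radii0: np.ndarray, vr, times: np.ndarray) -> np.ndarray:
    """Integrate dr/dt = v_r(r, t) with an RK2 midpoint step per frame."""
    out = np.empty((len(times), len(radii0)))
    out[0] = radii0
    r = radii0.astype(float).copy()
    for k in range(len(times) - 1):
        dt = times[k + 1] - times[k]
        k1 = vr(r, times[k])
        k2 = vr(np.clip(r + 0.5 * dt * k1, 0, None), times[k] + 0.5 * dt)
        r = np.clip(r + dt * k2, 0.0, None)
        out[k + 1] = r
    return out


def _particle_flux_counts(radii: np.ndarray, r_edges: np.ndarray,
                          dt_s: float) -> np.ndarray:
    """Net inward particle crossings per frame pair per radius (counts/pair).

    ``radii`` is (n_frames, n_particles).  A particle inside radius r at
    frame k+1 but not at frame k crossed inward; the net count is the change
    in the number of particles within r.
    """
    n_frames = radii.shape[0]
    inside = radii[..., None] <= r_edges[None, None, :]   # (T, N, E)
    counts = inside.sum(axis=1).astype(float)             # (T, E)
    return counts[1:] - counts[:-1]


def make_aster_scene(params: SceneParams, model: AsterModel,
                     channels: Sequence[ChannelSpec],
                     ) -> tuple[ImageStack, GroundTruth]:
    """Render a growing-aster scene with textured, advected channels.

    Returns the corrupted image stack and a :class:`GroundTruth` carrying
    the exact flow field, the R(t) table, particle records and (when a
    channel requests ``target_peak_flux``) the calibrated flux map.
    """
    if not channels:
        raise ValueError("at least one channel spec required")
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names")
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    t = params.times
    dt = params.frame_interval
    mtoc = _mtoc_trajectory(params, model)
    half_x, half_y = params.extent_um[1] / 2, params.extent_um[0] / 2
    if np.any(mtoc.x < 0) or np.any(mtoc.x > 2 * half_x) or \
       np.any(mtoc.y < 0) or np.any(mtoc.y > 2 * half_y):
        warnings.warn("MTOC trajectory leaves the image")
    vr = _radial_velocity_profile(model)
    R_table = AsterRadiusTable(t, np.minimum(model.R(t),
                                             max(half_x, half_y) * math.sqrt(2)),
                               method="prescribed")
    gt = GroundTruth(params=params, model=model, mtoc=mtoc,
                     aster_radius=R_table, velocity_profile=vr)
    if model.peripheral_depletion > 0:
        gt.depletion_center = lambda tt: float(np.asarray(model.R(tt))) - \
            model.band_width / 2.0

    clean = np.zeros((params.n_frames, len(channels), ny, nx))
    kappa = _enrichment_bin_factor(model)

    for ci, spec in enumerate(channels):
        tex = bandlimited_texture(rng, (ny, nx), spec.texture_mean,
                                  spec.texture_contrast)
        tau = (spec.turnover_tau if spec.turnover_tau is not None
               else params.texture_turnover_tau)
        alpha = 1.0 - math.exp(-dt / tau) if np.isfinite(tau) else 0.0

        frames = np.empty((params.n_frames, ny, nx))
        cur = tex
        for k in range(params.n_frames):
            if k > 0:
                if spec.advected:
                    cx, cy = mtoc.interp(t[k])
                    rr, xx, yy = _radius_grid(params, cx, cy)
                    v = vr(rr, t[k])
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ex = np.where(rr > 0, (xx - cx) / rr, 0.0)
                        ey = np.where(rr > 0, (yy - cy) / rr, 0.0)
                    u_px = v * ex * dt / params.pixel_size
                    v_px = v * ey * dt / params.pixel_size
                    fresh_fill = bandlimited_texture(
                        rng, (ny, nx), spec.texture_mean, spec.texture_contrast)
                    cur = warp_backward(cur, u_px, v_px, fill=fresh_fill)
                if alpha > 0:
                    fresh = bandlimited_texture(
                        rng, (ny, nx), spec.texture_mean, spec.texture_contrast)
                    cur = (1.0 - alpha) * cur + alpha * fresh
            frame = cur.copy()
            cx, cy = mtoc.interp(t[k])
            rr, _, _ = _radius_grid(params, cx, cy)
            if spec.interior_step != 0.0:
                R = float(np.asarray(model.R(t[k])))
                edge = 1.0 / (1.0 + np.exp((rr - R) / 2.5))
                frame = frame * (1.0 + spec.interior_step * edge)
            if spec.apply_depletion and model.peripheral_depletion > 0:
                center = float(np.asarray(model.R(t[k]))) - model.band_width / 2
                if center > 0:
                    dep = tukey_band(rr, center, model.band_width,
                                     model.band_taper)
                    frame = frame * (1.0 - model.peripheral_depletion * dep)
            if spec.apply_enrichment and model.central_enrichment > 1:
                ramp = t[k] / t[-1] if t[-1] > 0 else 1.0
                amp = (model.central_enrichment - 1.0) * spec.texture_mean \
                    / kappa * ramp
                frame = frame + amp * np.exp(-rr ** 2 /
                                             (2 * model.enrichment_sigma ** 2))
            frames[k] = frame
        clean[:, ci] = frames
        gt.extras[f"static_total_{spec.name}"] = float(tex.sum())

        if spec.n_particles > 0:
            _add_particle_component(clean[:, ci], params, model, spec, vr,
                                    mtoc, rng, gt)

    corrupted, bleach, ff = corrupt_stack(clean, params, rng)
    gt.bleach_factors = bleach
    gt.flatfield = ff
    stack = ImageStack(corrupted, params.pixel_size, params.frame_interval,
                       names)
    gt.trajectories = [mtoc]
    return stack, gt


def _enrichment_bin_factor(model: AsterModel) -> float:
    """Mean of exp(-r^2/2s^2) over the disk r < b, area-weighted.

    Calibrates the central accumulation so the innermost annular-bin readout
    equals the requested fold (closed form of the area integral).
    """
    b = model.enrichment_ref_radius
    s = model.enrichment_sigma
    return float(2 * s * s / (b * b) * (1.0 - math.exp(-b * b / (2 * s * s))))


def _add_particle_component(channel_frames: np.ndarray, params: SceneParams,
                            model: AsterModel, spec: ChannelSpec, vr,
                            mtoc: Trajectory, rng: np.random.Generator,
                            gt: GroundTruth) -> None:
    """Simulate, calibrate and render the conservative particle component."""
    from .core import MassTransportMap

    ny, nx = params.image_shape
    t = params.times
    dt_min = params.frame_interval / 60.0
    # uniform over the image area
    x0 = rng.uniform(0, nx * params.pixel_size, spec.n_particles)
    y0 = rng.uniform(0, ny * params.pixel_size, spec.n_particles)
    cx, cy = mtoc.interp(t[0])
    r0 = np.hypot(x0 - cx, y0 - cy)
    theta = np.arctan2(y0 - cy, x0 - cx)
    radii = _advect_radii(r0, vr, t)                     # (T, N)
    r_edges = np.arange(10.0, np.hypot(nx, ny) * params.pixel_size / 2 + 10,
                        10.0)
    crossings = _particle_flux_counts(radii, r_edges, params.frame_interval)

    static_total = gt.extras[f"static_total_{spec.name}"]
    if spec.particle_weight is not None:
        w = spec.particle_weight
    elif spec.target_peak_flux is not None:
        # solve  w * peak_rate = tau * (static_total + w * n_particles)
        peak_rate = crossings.max() / dt_min             # counts per minute
        tau_frac = spec.target_peak_flux / 100.0
        denom = peak_rate - tau_frac * spec.n_particles
        if denom <= 0:
            raise ValueError("target flux unreachable with this particle count")
        w = tau_frac * static_total / denom
    else:
        w = spec.texture_mean  # arbitrary visible default
    total = static_total + w * spec.n_particles
    flux = MassTransportMap(r_edges, 0.5 * (t[1:] + t[:-1]),
                            crossings * w / total * 100.0 / dt_min)
    # advective flux rho(r,t) * v_r(r,t) * 2*pi*r from the actual particle
    # density (the sweeping band dilutes the mobile density below its
    # initial uniform value, so rho must be measured, not assumed)
    ring = 5.0
    ana = np.empty_like(flux.flux)
    for k in range(ana.shape[0]):
        tm = 0.5 * (t[k] + t[k + 1])
        v_here = vr(r_edges, tm)
        for j, re_ in enumerate(r_edges):
            n_ring = 0.5 * (
                np.count_nonzero(np.abs(radii[k] - re_) <= ring) +
                np.count_nonzero(np.abs(radii[k + 1] - re_) <= ring))
            lin_dens = n_ring / (2 * ring)       # particles per µm of radius
            ana[k, j] = (-v_here[j]) * lin_dens * w / total * 100.0 * 60.0
    gt.analytic_flux = MassTransportMap(r_edges, flux.t, ana)
    gt.flux_map = flux
    gt.particle_radii = radii
    gt.particle_weight = w
    gt.static_total = static_total
    for k in range(params.n_frames):
        ck = mtoc.interp(t[k])
        xs = ck[0] + radii[k] * np.cos(theta)
        ys = ck[1] + radii[k] * np.sin(theta)
        channel_frames[k] += render_spots((ny, nx), params.pixel_size, xs, ys,
                                          w, spec.particle_sigma,
                                          normalize="sum")


# ---------------------------------------------------------------------------
# cloud scenes
# ---------------------------------------------------------------------------


def make_cloud_sequence(params: SceneParams, cloud: CloudModel,
                        mtoc_traj: Trajectory | None = None,
                        ) -> tuple[ImageStack, GroundTruth]:
    """Photo-released fluorescein cloud diffusing away from a bright MTOC."""
    t = params.times
    if not (t[0] <= cloud.release_time <= t[-1]):
        raise ValueError("release_time outside the sequence")
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    if mtoc_traj is None:
        cx, cy = params.center_um
        mtoc_traj = Trajectory(0, np.arange(params.n_frames), t,
                               np.full_like(t, cx), np.full_like(t, cy),
                               label="mtoc")
    rel = (np.array(cloud.release_position, dtype=float)
           if cloud.release_position is not None
           else mtoc_traj.interp(cloud.release_time))
    drift = np.asarray(cloud.drift_velocity, dtype=float)

    sigma_sq = np.asarray(cloud.sigma_sq(t), dtype=float)
    centers = rel[None, :] + drift[None, :] * \
        np.maximum(t - cloud.release_time, 0.0)[:, None]
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    xx *= params.pixel_size
    yy *= params.pixel_size
    clean = np.zeros((params.n_frames, 1, ny, nx))
    for k in range(params.n_frames):
        frame = np.zeros((ny, nx))
        if t[k] >= cloud.release_time:
            rho2 = (xx - centers[k, 0]) ** 2 + (yy - centers[k, 1]) ** 2
            frame += cloud.amplitude * np.exp(-rho2 / (2 * sigma_sq[k]))
        mx, my = mtoc_traj.interp(t[k])
        frame += render_spots((ny, nx), params.pixel_size, [mx], [my],
                              cloud.mtoc_amplitude, cloud.mtoc_sigma)
        clean[k, 0] = frame
    corrupted, bleach, ff = corrupt_stack(clean, params, rng)
    stack = ImageStack(corrupted, params.pixel_size, params.frame_interval,
                       ["fluorescein"])
    gt = GroundTruth(params=params, cloud=cloud, mtoc=mtoc_traj,
                     sigma_sq=sigma_sq, cloud_centers=centers,
                     bleach_factors=bleach, flatfield=ff,
                     trajectories=[mtoc_traj])
    return stack, gt


# ---------------------------------------------------------------------------
# MTOC separation fields (trajectory tables, no rendering)
# ---------------------------------------------------------------------------


def make_mtoc_field(n_mtocs: int, domain: tuple[float, float] = (600.0, 600.0),
                    speed_model: tuple[float, float] = (-0.05, 8.0),
                    d0_range: tuple[float, float] = (40.0, 120.0),
                    n_frames: int = 10, frame_interval: float = 60.0,
                    jitter_sd: float = 0.0, seed: int = 0,
                    truncate_fraction: float = 0.0,
                    ):
    """Trajectories of MTOC pairs separating along their connecting axes.

    Each pair's true maximum separation speed is ``intercept + slope * d0``
    (µm/min; the ``speed_model`` is (slope, intercept)), realised as constant
    symmetric recession along the pair axis plus optional positional jitter.
    Pairs are labelled CPC-positive (label 1); Delaunay edges between
    different pairs receive label 0 downstream.  ``truncate_fraction`` of
    the MTOCs lose their trailing frames, emulating particles that exit the
    field of view mid-movie.

    Returns ``(trajectories, edge_label_table)`` where the table has columns
    ``id_a, id_b, cpc``.
    """
    import pandas as pd

    if n_mtocs < 3:
        raise ValueError("need at least 3 MTOCs for triangulation downstream")
    rng = np.random.default_rng(seed)
    slope, intercept = speed_model
    n_pairs = n_mtocs // 2
    # pair centres on a jittered grid so the field is not collinear
    g = int(math.ceil(math.sqrt(n_pairs)))
    wx, wy = domain
    cxs, cys = np.meshgrid(np.linspace(0.15, 0.85, g) * wx,
                           np.linspace(0.15, 0.85, g) * wy)
    centers = np.c_[cxs.ravel(), cys.ravel()][:n_pairs]
    centers += rng.uniform(-0.04, 0.04, centers.shape) * min(wx, wy)
    t = np.arange(n_frames) * frame_interval
    trajs: list[Trajectory] = []
    labels = []
    pid = 0
    for (cx, cy) in centers:
        d0 = rng.uniform(*d0_range)
        ang = rng.uniform(0, 2 * math.pi)
        u = np.array([math.cos(ang), math.sin(ang)])
        vmax = intercept + slope * d0      # µm/min
        half_sep = d0 / 2 + vmax / 2 / 60.0 * t
        a = np.c_[cx + u[0] * half_sep, cy + u[1] * half_sep]
        b = np.c_[cx - u[0] * half_sep, cy - u[1] * half_sep]
        for pos in (a, b):
            xy = pos + rng.normal(0, jitter_sd, pos.shape)
            trajs.append(Trajectory(pid, np.arange(n_frames), t,
                                    xy[:, 0], xy[:, 1]))
            pid += 1
        labels.append((pid - 2, pid - 1, 1.0))
    # leftover single MTOC if n_mtocs is odd: static bystander
    if n_mtocs % 2:
        xy = rng.uniform(0.1, 0.9, 2) * np.array([wx, wy])
        trajs.append(Trajectory(pid, np.arange(n_frames), t,
                                np.full(n_frames, xy[0]) +
                                rng.normal(0, jitter_sd, n_frames),
                                np.full(n_frames, xy[1]) +
                                rng.normal(0, jitter_sd, n_frames)))
    if truncate_fraction > 0:
        n_trunc = int(round(truncate_fraction * len(trajs)))
        for tr in rng.choice(len(trajs), size=n_trunc, replace=False):
            keep = rng.integers(max(3, n_frames // 2), n_frames)
            trajs[tr] = Trajectory(trajs[tr].id, trajs[tr].frames[:keep],
                                   trajs[tr].t[:keep], trajs[tr].x[:keep],
                                   trajs[tr].y[:keep])
    table = pd.DataFrame(labels, columns=["id_a", "id_b", "cpc"])
    # reject degenerate configurations
    pts = np.array([[tr.x[0], tr.y[0]] for tr in trajs])
    if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        raise ValueError("collinear MTOC field; triangulation impossible")
    return trajs, table


# ---------------------------------------------------------------------------
# bead scenes
# ---------------------------------------------------------------------------


def make_bead_scene(params: SceneParams, model: AsterModel,
                    bead_speed_inside: float, n_beads: int,
                    bead_radii: tuple[float, float] = (40.0, 80.0),
                    jitter_sd: float = 0.3, bead_amplitude: float = 1500.0,
                    bead_sigma: float = 1.0, mtoc_amplitude: float = 3000.0,
                    absorb_radius: float = 3.0, seed: int | None = None,
                    ) -> tuple[ImageStack, GroundTruth]:
    """Dynein-coated beads captured and transported by a growing aster.

    Each bead sits still (plus jitter) until the aster periphery R(t)
    reaches it, then moves radially inward at ``bead_speed_inside`` (µm/s,
    positive = inward) until it is absorbed at ``absorb_radius`` from the
    MTOC, after which it merges with the bright MTOC blob and is no longer
    rendered separately.
    """
    if bead_speed_inside < 0:
        raise ValueError("bead_speed_inside must be >= 0 (positive = inward)")
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    t = params.times
    mtoc = _mtoc_trajectory(params, model)
    r_init = rng.uniform(*bead_radii, n_beads)
    if np.any(r_init <= model.R(t[0])):
        raise ValueError("beads must start outside the initial aster radius")
    theta = (np.arange(n_beads) + rng.uniform()) * 2 * math.pi / n_beads
    growth = model.growth_rate / 60.0
    entry = (r_init - model.r0) / growth if growth > 0 else \
        np.full(n_beads, np.inf)
    radii = np.empty((params.n_frames, n_beads))
    for k, tk in enumerate(t):
        moved = np.maximum(tk - entry, 0.0) * bead_speed_inside
        radii[k] = np.clip(r_init - moved, 0.0, None)
    absorbed = radii <= absorb_radius
    clean = np.zeros((params.n_frames, 1, ny, nx))
    trajs: list[Trajectory] = []
    xs_all = np.empty((params.n_frames, n_beads))
    ys_all = np.empty((params.n_frames, n_beads))
    for k, tk in enumerate(t):
        cxy = mtoc.interp(tk)
        xs = cxy[0] + radii[k] * np.cos(theta) + rng.normal(0, jitter_sd,
                                                            n_beads)
        ys = cxy[1] + radii[k] * np.sin(theta) + rng.normal(0, jitter_sd,
                                                            n_beads)
        xs_all[k], ys_all[k] = xs, ys
        live = ~absorbed[k]
        frame = render_spots((ny, nx), params.pixel_size, xs[live], ys[live],
                             bead_amplitude, bead_sigma)
        frame += render_spots((ny, nx), params.pixel_size, [cxy[0]], [cxy[1]],
                              mtoc_amplitude, bead_sigma * 1.5)
        clean[k, 0] = frame
    corrupted, bleach, ff = corrupt_stack(clean, params, rng)
    stack = ImageStack(corrupted, params.pixel_size, params.frame_interval,
                       ["beads"])
    entry_times: dict[int, float] = {}
    for b in range(n_beads):
        live = np.nonzero(~absorbed[:, b])[0]
        trajs.append(Trajectory(b + 1, live, t[live], xs_all[live, b],
                                ys_all[live, b], label="bead"))
        entry_times[b + 1] = float(entry[b])
    gt = GroundTruth(params=params, model=model, mtoc=mtoc,
                     trajectories=[mtoc] + trajs,
                     aster_radius=AsterRadiusTable(t, np.asarray(model.R(t)),
                                                   "prescribed"),
                     bleach_factors=bleach, flatfield=ff,
                     entry_times=entry_times,
                     extras={"bead_speed_inside": bead_speed_inside,
                             "absorb_radius": absorb_radius})
    return stack, gt


# ---------------------------------------------------------------------------
# simple particle scenes: oscillation, co-moving network
# ---------------------------------------------------------------------------


def make_oscillation_scene(params: SceneParams, diameter: float = 25.0,
                           speed: float = 1.0, amplitude: float = 2000.0,
                           spot_sigma: float = 1.0,
                           ) -> tuple[ImageStack, GroundTruth]:
    """Bright MTOC moving on a circle at constant speed (dynein-coverslip
    oscillation regime)."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    t = params.times
    R = diameter / 2.0
    omega = speed / R
    cx, cy = params.center_um
    xs = cx + R * np.cos(omega * t)
    ys = cy + R * np.sin(omega * t)
    clean = np.zeros((params.n_frames, 1, ny, nx))
    for k in range(params.n_frames):
        clean[k, 0] = render_spots((ny, nx), params.pixel_size, [xs[k]],
                                   [ys[k]], amplitude, spot_sigma)
    corrupted, bleach, ff = corrupt_stack(clean, params, rng)
    stack = ImageStack(corrupted, params.pixel_size, params.frame_interval,
                       ["mtoc"])
    traj = Trajectory(0, np.arange(params.n_frames), t, xs, ys, label="mtoc")
    gt = GroundTruth(params=params, mtoc=traj, trajectories=[traj],
                     bleach_factors=bleach, flatfield=ff,
                     extras={"speed": speed, "diameter": diameter})
    return stack, gt


def make_comoving_scene(params: SceneParams,
                        velocity: tuple[float, float] = (0.1167, 0.0),
                        texture_mean: float = 2000.0,
                        texture_contrast: float = 0.25,
                        mtoc_amplitude: float = 3000.0,
                        ) -> tuple[ImageStack, GroundTruth]:
    """Network texture and MTOC translating rigidly at the same velocity
    (the separation-movement regime where networks co-move with the MTOC)."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    t = params.times
    vx, vy = velocity
    cx, cy = params.center_um
    xs = cx + vx * t - vx * t[-1] / 2
    ys = cy + vy * t - vy * t[-1] / 2
    tex = bandlimited_texture(rng, (ny, nx), texture_mean, texture_contrast)
    dt = params.frame_interval
    alpha = (1.0 - math.exp(-dt / params.texture_turnover_tau)
             if np.isfinite(params.texture_turnover_tau) else 0.0)
    u_px = np.full((ny, nx), vx * dt / params.pixel_size)
    v_px = np.full((ny, nx), vy * dt / params.pixel_size)
    clean = np.zeros((params.n_frames, 2, ny, nx))
    cur = tex
    for k in range(params.n_frames):
        if k > 0:
            fresh = bandlimited_texture(rng, (ny, nx), texture_mean,
                                        texture_contrast)
            cur = warp_backward(cur, u_px, v_px, fill=fresh)
            if alpha > 0:
                fresh2 = bandlimited_texture(rng, (ny, nx), texture_mean,
                                             texture_contrast)
                cur = (1 - alpha) * cur + alpha * fresh2
        clean[k, 0] = cur
        clean[k, 1] = render_spots((ny, nx), params.pixel_size, [xs[k]],
                                   [ys[k]], mtoc_amplitude, 1.0)
    corrupted, bleach, ff = corrupt_stack(clean, params, rng)
    stack = ImageStack(corrupted, params.pixel_size, params.frame_interval,
                       ["network", "mtoc"])
    traj = Trajectory(0, np.arange(params.n_frames), t, xs, ys, label="mtoc")
    gt = GroundTruth(params=params, mtoc=traj, trajectories=[traj],
                     bleach_factors=bleach, flatfield=ff,
                     extras={"velocity": (vx, vy)})
    return stack, gt
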