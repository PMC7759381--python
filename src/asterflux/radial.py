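"""Radial intensity profiles, aster-periphery estimation, enrichment
statistics and the annular-bin mass-transport (flux) analysis.

The mass-transport map quantifies net movement of fluorescence toward the
MTOC: per frame, the *summed* intensity in 10 µm annular bins about the
(moving) MTOC is accumulated outward into C(r, t), and the net inward flux
across radius r between consecutive frames is

    F(r, t) = [C(r, t+dt) - C(r, t)] / dt,

scaled to percent of the ROI total per minute (positive = inward).  Direct
pixel sums are used rather than mean x ideal-annulus-area so image-edge
clipping introduces no area bias.  After photobleach normalization the ROI
total is conserved, so the flux at the outermost radius is ~0 and the
inter-frame changes sum to zero over all annuli.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .core import (AsterRadiusTable, ImageStack, MassTransportMap,
                   RadialProfile, Roi, Trajectory)
from .imgprep import outside_aster_mask


def _radius_image(shape, pixel_size, center):
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return np.hypot(xx * pixel_size - center[0], yy * pixel_size - center[1])


def _sector_mask(shape, pixel_size, center, sector):
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    ang = np.mod(np.arctan2(yy * pixel_size - center[1],
                            xx * pixel_size - center[0]), 2 * math.pi)
    lo, hi = np.mod(sector[0], 2 * math.pi), np.mod(sector[1], 2 * math.pi)
    if lo <= hi:
        return (ang >= lo) & (ang <= hi)
    return (ang >= lo) | (ang <= hi)


def radial_profile(stack: ImageStack, channel: int | str,
                   center_traj: Trajectory, bin_width: float = 10.0,
                   normalize_outside: bool = False,
                   R: AsterRadiusTable | None = None,
                   r_max: float | None = None,
                   annulus: tuple[float, float] = (10.0, 30.0),
                   ) -> RadialProfile:
    """Mean intensity in annular bins about the (moving) centre, per frame.

    With ``normalize_outside`` each frame's profile is divided by the mean
    intensity in the outside-aster annulus (R(t)+10 to R(t)+30 µm), the
    photobleach-robust normalization used for enrichment/depletion readouts:
    the profile value far outside the aster is then ~1 at every time.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if normalize_outside and R is None:
        raise ValueError("normalize_outside requires an R(t) table")
    imgs = stack.channel(channel)
    px = stack.pixel_size
    ny, nx = stack.shape
    if r_max is None:
        r_max = 0.5 * math.hypot(nx, ny) * px
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    values = np.full((stack.n_frames, nb), np.nan)
    counts = np.zeros((stack.n_frames, nb), dtype=int)
    for k, t in enumerate(stack.times):
        c = center_traj.interp(t)
        if not (0 <= c[0] <= nx * px and 0 <= c[1] <= ny * px):
            raise ValueError("centre outside the image")
        rr = _radius_image((ny, nx), px, c)
        idx = np.minimum((rr / bin_width).astype(int), nb - 1)
        flat = idx.ravel()
        w = imgs[k].ravel()
        cnt = np.bincount(flat, minlength=nb)
        tot = np.bincount(flat, weights=w, minlength=nb)
        has = cnt > 0
        values[k, has] = tot[has] / cnt[has]
        counts[k] = cnt
        if normalize_outside:
            m = outside_aster_mask((ny, nx), px, c, float(R(t)), annulus)
            ref = imgs[k][m].mean() if m.any() else np.nan
            values[k] /= ref
    return RadialProfile(centers, values, bin_width, stack.times,
                         normalized_outside=normalize_outside, counts=counts)


def detect_aster_radius(stack: ImageStack, mt_channel: int | str,
                        center_traj: Trajectory, bin_width: float = 5.0,
                        smooth_bins: int = 3, min_contrast: float = 0.1,
                        monotone: bool = False) -> AsterRadiusTable:
    """Estimate R(t) from the interior/exterior plateau contrast of the MT
    channel.

    Per frame, R is the largest radius at which the smoothed radial profile
    crosses the midpoint between the interior plateau (median of the inner
    third of bins) and the exterior plateau (median of the outermost 15%).
    Frames whose plateau contrast is below ``min_contrast`` (relative to the
    exterior level) yield a missing R.  ``monotone`` enforces a
    non-decreasing radius by a running maximum.
    """
    prof = radial_profile(stack, mt_channel, center_traj, bin_width)
    t = prof.t
    Rs = np.full(len(t), np.nan)
    nb = len(prof.bin_centers)
    for k in range(len(t)):
        p = prof.values[k].copy()
        good = np.isfinite(p)
        if good.sum() < 6:
            continue
        if smooth_bins > 1:
            from scipy.ndimage import uniform_filter1d
            p[good] = uniform_filter1d(p[good], smooth_bins, mode="nearest")
        inner = np.nanmedian(p[: nb // 3])
        outer = np.nanmedian(p[int(nb * 0.85):])
        if not np.isfinite(inner) or not np.isfinite(outer):
            continue
        if abs(inner - outer) < min_contrast * max(abs(outer), 1e-12):
            continue
        mid = 0.5 * (inner + outer)
        above = (p - mid) * np.sign(inner - outer) > 0  # interior side
        cross = np.nonzero(above[:-1] & ~above[1:])[0]
        if len(cross) == 0:
            continue
        j = cross[-1]
        # linear interpolation between bin centres
        x0, x1 = prof.bin_centers[j], prof.bin_centers[j + 1]
        y0, y1 = p[j], p[j + 1]
        Rs[k] = x0 + (mid - y0) / (y1 - y0) * (x1 - x0) if y1 != y0 else x0
    if monotone:
        running = -np.inf
        for k in range(len(Rs)):
            if np.isfinite(Rs[k]):
                running = max(running, Rs[k])
                Rs[k] = running
    return AsterRadiusTable(t, Rs, method="plateau-midpoint")


def mass_transport_map(stack: ImageStack, channel: int | str,
                       center_traj: Trajectory, roi: Roi | None = None,
                       bin_width: float = 10.0,
                       sector: tuple[float, float] | None = None,
                       conservation_tol: float = 0.01,
                       ) -> MassTransportMap:
    """Net inward flux of fluorescence across MTOC-centred circles.

    The stack must be preprocessed (background, flat-field, photobleach
    normalization); a drift of the per-frame ROI total beyond
    ``conservation_tol`` (relative) triggers a warning with its magnitude.
    Annuli are recentred on the MTOC each frame, so the cumulative profiles
    are differenced in the MTOC frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    imgs = stack.channel(channel)
    px = stack.pixel_size
    ny, nx = stack.shape
    mask = roi.mask if roi is not None else np.ones((ny, nx), bool)
    r_max = 0.5 * math.hypot(nx, ny) * px
    edges = np.arange(bin_width, r_max + bin_width, bin_width)
    nb = len(edges)
    C = np.empty((stack.n_frames, nb))
    totals = np.empty(stack.n_frames)
    for k, t in enumerate(stack.times):
        c = center_traj.interp(t)
        rr = _radius_image((ny, nx), px, c)
        sel = mask
        if sector is not None:
            sel = sel & _sector_mask((ny, nx), px, c, sector)
        idx = np.minimum((rr[sel] / bin_width).astype(int), nb - 1)
        sums = np.bincount(idx, weights=imgs[k][sel], minlength=nb)
        C[k] = np.cumsum(sums)
        totals[k] = C[k, -1]
    drift = (totals.max() - totals.min()) / totals.mean()
    if drift > conservation_tol:
        warnings.warn(f"ROI total drifts by {drift:.2%}: ROI may not enclose "
                      "the aster at all times or bleaching is uncorrected")
    dt_min = stack.frame_interval / 60.0
    flux = (C[1:] - C[:-1]) / totals.mean() * 100.0 / dt_min
    t_mid = 0.5 * (stack.times[1:] + stack.times[:-1])
    return MassTransportMap(edges, t_mid, flux, sector=sector)


def enrichment_timecourse(profile: RadialProfile,
                          inner_radius: float = 10.0):
    """Fold-enrichment within ``inner_radius`` of the centre over time.

    Requires an outside-normalized profile.  Returns a dict with the time
    series, the fraction of increasing steps of its 3-point moving average
    (monotonicity diagnostic) and the final value.
    """
    if not profile.normalized_outside:
        raise ValueError("profile must be normalized to the outside-aster "
                         "mean")
    if inner_radius < profile.bin_width:
        raise ValueError("inner_radius must be >= bin_width")
    sel = profile.bin_centers < inner_radius
    w = profile.counts[:, sel].astype(float) if profile.counts is not None \
        else np.ones((profile.values.shape[0], sel.sum()))
    vals = np.nansum(profile.values[:, sel] * w, axis=1) / w.sum(axis=1)
    kernel = np.ones(3) / 3
    sm = np.convolve(vals, kernel, mode="valid")
    steps = np.diff(sm)
    frac_up = float((steps > 0).mean()) if len(steps) else float("nan")
    return {"t": profile.t, "enrichment": vals,
            "fraction_increasing": frac_up, "final": float(vals[-1]),
            "monotone_increasing": bool(np.all(steps > 0))}


def band_bin_value(profile: RadialProfile, band_center: float,
                   frame: int) -> float:
    """Normalized profile value of the bin containing ``band_center``."""
    j = int(np.argmin(np.abs(profile.bin_centers - band_center)))
    return float(profile.values[frame, j])
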