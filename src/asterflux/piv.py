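"""Window-correlation particle image velocimetry and velocity-map tools.

Single-pass FFT cross-correlation per interrogation window with a 3-point
Gaussian sub-pixel peak fit (parabolic fallback when a correlation value is
non-positive), a normalized-median outlier test on the 8-neighbourhood,
projection of vector fields onto a line, reference-frame subtraction, and
radial binning about a moving centre.

Outliers are masked, never interpolated: an invalid vector contributes to
no downstream statistic.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import FlowField, ImageStack, ProjectedVelocityMap, Trajectory


# ---------------------------------------------------------------------------
# core correlation engine
# ---------------------------------------------------------------------------


def _subpixel_1d(cm: np.ndarray, c0: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Vectorised 3-point peak interpolation (Gaussian, parabolic fallback)."""
    delta = np.zeros_like(c0)
    pos = (cm > 0) & (c0 > 0) & (cp > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm, l0, lp = np.log(cm[pos]), np.log(c0[pos]), np.log(cp[pos])
        den = 2 * lm - 4 * l0 + 2 * lp
        g = np.where(den != 0, (lm - lp) / den, 0.0)
        delta[pos] = g
        par = ~pos
        den2 = 2 * (cm[par] - 2 * c0[par] + cp[par])
        p = np.where(den2 != 0, (cm[par] - cp[par]) / den2, 0.0)
        delta[par] = p
    return np.clip(delta, -1.0, 1.0)


def _correlate_windows(a: np.ndarray, b: np.ndarray):
    """Displacement of ``b`` relative to ``a`` for a batch of windows.

    ``a, b`` have shape (n, w, w).  Returns (dx, dy, valid) in pixels.
    """
    n, w, _ = a.shape
    a = a - a.mean(axis=(1, 2), keepdims=True)
    b = b - b.mean(axis=(1, 2), keepdims=True)
    sa = a.std(axis=(1, 2))
    sb = b.std(axis=(1, 2))
    valid = (sa > 1e-12) & (sb > 1e-12)
    size = 2 * w
    fa = np.fft.rfft2(a, s=(size, size))
    fb = np.fft.rfft2(b, s=(size, size))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(size, size))
    corr = np.fft.fftshift(corr, axes=(1, 2))
    # limit the search to |d| <= w/4 (the usual one-quarter rule); beyond
    # it the unbiased normalization amplifies spurious large-lag peaks
    ctr = size // 2
    half = w // 4
    sub = corr[:, ctr - half:ctr + half + 1, ctr - half:ctr + half + 1]
    # unbiased normalization: zero-padded linear correlation sums over
    # (w-|dy|)(w-|dx|) terms, a tent envelope that skews the peak toward
    # zero lag by ~sigma_corr^2/w px; divide it out
    lag = np.arange(-half, half + 1)
    env = (w - np.abs(lag))[:, None] * (w - np.abs(lag))[None, :]
    sub = sub / env[None, :, :]
    flat = sub.reshape(n, -1)
    idx = np.argmax(flat, axis=1)
    iy, ix = np.unravel_index(idx, sub.shape[1:])
    # clamp away from the border of the search region for the 3-point fit
    iy = np.clip(iy, 1, sub.shape[1] - 2)
    ix = np.clip(ix, 1, sub.shape[2] - 2)
    rows = np.arange(n)
    c0 = sub[rows, iy, ix]
    dy = (iy - half) + _subpixel_1d(sub[rows, iy - 1, ix], c0,
                                    sub[rows, iy + 1, ix])
    dx = (ix - half) + _subpixel_1d(sub[rows, iy, ix - 1], c0,
                                    sub[rows, iy, ix + 1])
    return dx, dy, valid


def compute_flow(stack: ImageStack, channel: int | str = 0,
                 window_size: int = 32, overlap: float = 0.5,
                 frame_pairs: Sequence[tuple[int, int]] | None = None,
                 ) -> list[FlowField]:
    """PIV flow fields for consecutive frame pairs of one channel.

    Displacements are converted to µm/s with the stack calibration.  Frame
    intervals above 20 s risk losing inter-frame correlation in turning-over
    networks and trigger a warning.
    """
    if window_size < 16:
        raise ValueError("window_size must be >= 16 px")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if stack.frame_interval > 20:
        warnings.warn("frame interval > 20 s: inter-frame correlation may be "
                      "too low for reliable PIV")
    imgs = stack.channel(channel)
    ny, nx = stack.shape
    step = max(1, int(round(window_size * (1.0 - overlap))))
    y0s = np.arange(0, ny - window_size + 1, step)
    x0s = np.arange(0, nx - window_size + 1, step)
    gy, gx = np.meshgrid(y0s, x0s, indexing="ij")
    cy_um = (gy + (window_size - 1) / 2) * stack.pixel_size
    cx_um = (gx + (window_size - 1) / 2) * stack.pixel_size
    if frame_pairs is None:
        frame_pairs = [(k, k + 1) for k in range(stack.n_frames - 1)]
    fields = []
    for (i, j) in frame_pairs:
        wa = sliding_window_view(imgs[i], (window_size, window_size))
        wb = sliding_window_view(imgs[j], (window_size, window_size))
        a = wa[gy.ravel(), gx.ravel()]
        b = wb[gy.ravel(), gx.ravel()]
        dx, dy, valid = _correlate_windows(a, b)
        dt = (j - i) * stack.frame_interval
        scale = stack.pixel_size / dt
        u = (dx * scale).reshape(gy.shape)
        v = (dy * scale).reshape(gy.shape)
        fields.append(FlowField(
            x=cx_um, y=cy_um, u=u, v=v, valid=valid.reshape(gy.shape),
            window_size=window_size, overlap=overlap, frame_pair=(i, j),
            t=0.5 * (stack.times[i] + stack.times[j])))
    return fields


# ---------------------------------------------------------------------------
# outlier filtering (normalized median test)
# ---------------------------------------------------------------------------


def _neighbor_stack(arr: np.ndarray) -> np.ndarray:
    """(8, ny, nx) stack of the 8-neighbourhood, NaN-padded at the border."""
    p = np.pad(arr, 1, constant_values=np.nan)
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]
    ny, nx = arr.shape
    return np.stack([p[1 + di:1 + di + ny, 1 + dj:1 + dj + nx]
                     for di, dj in shifts])


def filter_outliers(field: FlowField, threshold: float = 2.0,
                    eps: float = 0.1) -> FlowField:
    """Normalized median test on the 8-neighbourhood.

    For each component, the residual is |v - median(neighbours)| divided by
    (median of the neighbours' own residuals + eps); vectors whose residual
    exceeds ``threshold`` in either component are marked invalid.  Already
    invalid vectors are excluded from neighbour statistics.  The test is
    idempotent because invalidated vectors leave the neighbourhoods.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    valid = field.valid.copy()
    flagged = np.zeros_like(valid)
    for comp in (field.u, field.v):
        c = np.where(valid, comp, np.nan)
        nb = _neighbor_stack(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(nb, axis=0)
            res_nb = np.nanmedian(np.abs(nb - med), axis=0)
            r = np.abs(c - med) / (res_nb + eps)
        flagged |= np.where(np.isfinite(r), r > threshold, False)
    new_valid = valid & ~flagged
    return FlowField(field.x, field.y, field.u, field.v, new_valid,
                     field.window_size, field.overlap, field.frame_pair,
                     field.t)


def outlier_fraction(fields: Sequence[FlowField],
                     filtered: Sequence[FlowField]) -> float:
    before = sum(f.valid.sum() for f in fields)
    after = sum(f.valid.sum() for f in filtered)
    return 1.0 - after / before if before else 0.0


# ---------------------------------------------------------------------------
# projections and sampling
# ---------------------------------------------------------------------------


def project_onto_line(field: FlowField, p1: np.ndarray, p2: np.ndarray,
                      corridor_halfwidth: float | None = None,
                      bin_width: float | None = None,
                      s_range: tuple[float, float] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project one flow field onto the line through p1 and p2.

    Valid vectors within ``corridor_halfwidth`` (default: one grid spacing)
    of the line contribute their component along the p1->p2 unit vector,
    binned along the signed distance ``s`` from the midpoint of p1, p2
    (positive toward p2).  Returns ``(s_centers, w, valid)``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("p1 and p2 must differ")
    e = (p2 - p1) / np.linalg.norm(p2 - p1)
    nvec = np.array([-e[1], e[0]])
    mid = 0.5 * (p1 + p2)
    dx = field.x - mid[0]
    dy = field.y - mid[1]
    s = dx * e[0] + dy * e[1]
    d = np.abs(dx * nvec[0] + dy * nvec[1])
    spacing = field.grid_spacing_um
    hw = corridor_halfwidth if corridor_halfwidth is not None else spacing
    bw = bin_width if bin_width is not None else spacing
    sel = (d <= hw) & field.valid
    if s_range is None:
        smax = max(abs(s.min()), abs(s.max()))
        s_range = (-smax, smax)
    edges = np.arange(s_range[0], s_range[1] + bw, bw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.full(len(centers), np.nan)
    if not sel.any():
        warnings.warn("empty projection corridor")
        return centers, w, np.zeros(len(centers), bool)
    proj = field.u * e[0] + field.v * e[1]
    idx = np.digitize(s[sel], edges) - 1
    ok = (idx >= 0) & (idx < len(centers))
    sums = np.bincount(idx[ok], weights=proj[sel][ok], minlength=len(centers))
    cnts = np.bincount(idx[ok], minlength=len(centers))
    has = cnts > 0
    w[has] = sums[has] / cnts[has]
    return centers, w, has


def project_map(fields: Sequence[FlowField], trajA: Trajectory,
                trajB: Trajectory, corridor_halfwidth: float | None = None,
                bin_width: float | None = None,
                s_range: tuple[float, float] | None = None,
                ) -> ProjectedVelocityMap:
    """Projected-velocity map over time along the (moving) A--B line."""
    if s_range is None:
        span = max(np.linalg.norm(trajA.interp(f.t) - trajB.interp(f.t))
                   for f in fields)
        s_range = (-span, span)
    rows, valids = [], []
    for f in fields:
        pa = trajA.interp(f.t)
        pb = trajB.interp(f.t)
        s, w, ok = project_onto_line(f, pa, pb, corridor_halfwidth,
                                     bin_width, s_range)
        rows.append(w)
        valids.append(ok)
    t = np.array([f.t for f in fields])
    return ProjectedVelocityMap(s, t, np.array(rows), np.array(valids),
                                reference="none")


def subtract_reference(pmap: ProjectedVelocityMap,
                       reference_velocity: Callable[[np.ndarray], np.ndarray],
                       name: str = "reference") -> ProjectedVelocityMap:
    """Subtract a time-dependent reference velocity (µm/s) from the map."""
    ref = np.asarray(reference_velocity(pmap.t), dtype=float)
    return ProjectedVelocityMap(pmap.s, pmap.t, pmap.w - ref[:, None],
                                pmap.valid, reference=name)


def sample_near_point(fields: Sequence[FlowField], point_traj: Trajectory,
                      radius: float = 15.0,
                      direction: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean PIV velocity in a disk around a (moving) point, per frame pair.

    Returns times and values: the speed (vector-mean magnitude) when
    ``direction`` is None, else the mean component along ``direction``.
    Times with no valid vector in the disk yield NaN.
    """
    if radius < fields[0].grid_spacing_um:
        raise ValueError("radius must be >= the PIV grid spacing")
    t = np.array([f.t for f in fields])
    out = np.full(len(fields), np.nan)
    for k, f in enumerate(fields):
        p = point_traj.interp(f.t)
        sel = (np.hypot(f.x - p[0], f.y - p[1]) <= radius) & f.valid
        if not sel.any():
            continue
        if direction is None:
            out[k] = math.hypot(f.u[sel].mean(), f.v[sel].mean())
        else:
            e = np.asarray(direction, float)
            e = e / np.linalg.norm(e)
            out[k] = (f.u[sel] * e[0] + f.v[sel] * e[1]).mean()
    return t, out


def radial_speed_map(fields: Sequence[FlowField], center_traj: Trajectory,
                     bin_width: float = 10.0,
                     sector: tuple[float, float] | None = None,
                     r_max: float | None = None):
    """Radial component and speed binned by distance from a moving centre.

    ``sector`` restricts vectors to an angular range (radians, measured from
    +x, y down).  Returns a dict with ``r_centers``, ``t``, ``radial``
    (signed, positive = outward) and ``speed`` arrays of shape
    ``(n_pairs, n_bins)``; empty bins are NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if r_max is None:
        f0 = fields[0]
        r_max = float(np.hypot(f0.x, f0.y).max())
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    radial = np.full((len(fields), nb), np.nan)
    speed = np.full((len(fields), nb), np.nan)
    t = np.array([f.t for f in fields])
    for k, f in enumerate(fields):
        c = center_traj.interp(f.t)
        dx, dy = f.x - c[0], f.y - c[1]
        r = np.hypot(dx, dy)
        sel = f.valid & (r > 0)
        if sector is not None:
            ang = np.mod(np.arctan2(dy, dx), 2 * math.pi)
            lo, hi = np.mod(sector[0], 2 * math.pi), np.mod(sector[1],
                                                            2 * math.pi)
            in_sector = ((ang >= lo) & (ang <= hi)) if lo <= hi else \
                ((ang >= lo) | (ang <= hi))
            sel &= in_sector
        if not sel.any():
            continue
        vr = (f.u * dx + f.v * dy)[sel] / r[sel]
        sp = np.hypot(f.u, f.v)[sel]
        idx = np.digitize(r[sel], edges) - 1
        ok = (idx >= 0) & (idx < nb)
        cnt = np.bincount(idx[ok], minlength=nb)
        has = cnt > 0
        radial[k, has] = np.bincount(idx[ok], weights=vr[ok],
                                     minlength=nb)[has] / cnt[has]
        speed[k, has] = np.bincount(idx[ok], weights=sp[ok],
                                    minlength=nb)[has] / cnt[has]
    return {"r_centers": centers, "t": t, "radial": radial, "speed": speed}
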