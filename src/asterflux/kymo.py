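"""Kymographs along the MTOC–MTOC line in moving reference frames.

Each row of a kymograph is the intensity sampled along a line through a
per-frame reference point, computationally translated so the reference
maps to s = 0.  Supported references: the midpoint between two MTOCs
(interaction-zone frame), one MTOC (oscillation frame), or the lab frame.
Bilinear interpolation, with averaging across a small perpendicular
half-width to suppress noise; out-of-image samples are NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import ImageStack, Kymograph, ProjectedVelocityMap, Trajectory


def line_kymograph(stack: ImageStack, channel: int | str,
                   trajA: Trajectory, trajB: Trajectory | None = None,
                   axis: tuple[float, float] | None = None,
                   reference: str = "midpoint", line_halfwidth: float = 2.0,
                   s_extent: float | None = None,
                   reorient: bool = True) -> Kymograph:
    """Intensity kymograph along the line through the MTOC(s).

    With two trajectories the line passes through both; ``reference``
    selects which point is held at s = 0 ('midpoint', 'mtoc' = A, or
    'lab' = the t0 midpoint, fixed).  With one trajectory a fixed ``axis``
    direction is required and the reference is the moving MTOC.  When
    ``reorient`` is False the line keeps its final-frame orientation.

    s is sampled at one pixel equivalent; positive s points from A toward B
    (or along ``axis``).  Annotation tracks give the per-row s-positions of
    the MTOCs.
    """
    imgs = stack.channel(channel)
    t = stack.times
    px = stack.pixel_size
    ny, nx = stack.shape
    if trajB is None and axis is None:
        raise ValueError("need either a second trajectory or a fixed axis")

    pa = trajA.interp(t)                      # (T, 2)
    if trajB is not None:
        pb = trajB.interp(t)
        dirs = pb - pa
    else:
        pb = None
        dirs = np.tile(np.asarray(axis, dtype=float), (len(t), 1))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("anchors coincide in some frame")
    dirs = dirs / norms
    if not reorient:
        dirs = np.tile(dirs[-1], (len(t), 1))

    if reference == "midpoint":
        if pb is None:
            raise ValueError("midpoint reference needs two trajectories")
        ref = 0.5 * (pa + pb)
    elif reference == "mtoc":
        ref = pa
    elif reference == "lab":
        ref0 = 0.5 * (pa[0] + pb[0]) if pb is not None else pa[0]
        ref = np.tile(ref0, (len(t), 1))
    else:
        raise ValueError(f"unknown reference {reference!r}")

    if s_extent is None:
        s_extent = 0.5 * float(np.hypot(nx, ny)) * px
    s = np.arange(-s_extent, s_extent + px, px)
    offsets = np.arange(-line_halfwidth, line_halfwidth + px, px)
    rows = np.empty((len(t), len(s)))
    ann_a = np.empty(len(t))
    ann_b = np.full(len(t), np.nan)
    for k in range(len(t)):
        e = dirs[k]
        nvec = np.array([-e[1], e[0]])
        base = ref[k][None, :] + s[:, None] * e[None, :]
        vals = np.empty((len(offsets), len(s)))
        for oi, off in enumerate(offsets):
            pts = base + off * nvec[None, :]
            coords = np.array([pts[:, 1] / px, pts[:, 0] / px])  # (row, col)
            vals[oi] = ndimage.map_coordinates(imgs[k], coords, order=1,
                                               mode="constant", cval=np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[k] = np.nanmean(vals, axis=0)
        ann_a[k] = float((pa[k] - ref[k]) @ e)
        if pb is not None:
            ann_b[k] = float((pb[k] - ref[k]) @ e)
    ann = {"mtoc_a": ann_a}
    if pb is not None:
        ann["mtoc_b"] = ann_b
    return Kymograph(s, t, rows, reference, ann)


def velocity_kymograph(pmap: ProjectedVelocityMap,
                       reference_velocity=None,
                       reference_position=None,
                       name: str = "reference") -> Kymograph:
    """Re-bin a projected-velocity map into a kymograph-shaped (s, t) frame.

    Subtracts ``reference_velocity(t)`` (µm/s) from every cell and, when
    ``reference_position(t)`` is given, shifts each row so the reference
    point sits at s = 0.  Invalid cells stay NaN (excluded, as PIV outliers
    are from any statistic).
    """
    w = pmap.w.copy()
    if reference_velocity is not None:
        w = w - np.asarray(reference_velocity(pmap.t), dtype=float)[:, None]
    s = pmap.s
    if reference_position is not None:
        shift = np.asarray(reference_position(pmap.t), dtype=float)
        ds = s[1] - s[0]
        out = np.full_like(w, np.nan)
        for k in range(w.shape[0]):
            n = int(round(shift[k] / ds))
            if n == 0:
                out[k] = w[k]
            elif n > 0:
                out[k, :-n or None] = w[k, n:]
            else:
                out[k, -n:] = w[k, :n]
        w = out
    bad = ~pmap.valid if pmap.valid.ndim == 2 else None
    if bad is not None and reference_position is None:
        w[bad] = np.nan
    return Kymograph(s, pmap.t, w, name, {})
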