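"""Preprocessing: background subtraction, flat-field correction, ROI
definition and photobleach normalization.

The documented order is subtract background -> flat-field correct ->
normalize bleaching, which exactly inverts the generator's corruption
order.  Photobleach normalization rescales every frame so a conserved
reference statistic (ROI total, or the mean intensity outside the aster)
equals its first-frame value.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import AsterRadiusTable, ImageStack, Roi


def subtract_background(stack: ImageStack, method: str = "percentile",
                        value: float = 1.0, smooth_sigma_px: float = 8.0,
                        ) -> tuple[ImageStack, list[float]]:
    """Subtract a per-channel constant background, clipping at zero.

    ``method='constant'`` subtracts ``value``; ``method='percentile'``
    estimates the background as the ``value``-th percentile of the first
    frame of each channel (default 1st percentile).  The percentile is
    taken on a heavily smoothed copy of the frame (``smooth_sigma_px``),
    otherwise read noise biases a low percentile downward by several noise
    SDs.  Returns the corrected stack and the per-channel estimates.
    """
    from scipy import ndimage

    out = stack.copy()
    estimates: list[float] = []
    for c in range(out.data.shape[1]):
        if method == "constant":
            if value < 0:
                raise ValueError("constant background must be >= 0")
            bg = float(value)
        elif method == "percentile":
            if not 0 < value < 50:
                raise ValueError("percentile must be in (0, 50)")
            ref = ndimage.gaussian_filter(out.data[0, c], smooth_sigma_px) \
                if smooth_sigma_px > 0 else out.data[0, c]
            bg = float(np.percentile(ref, value))
        else:
            raise ValueError(f"unknown method {method!r}")
        out.data[:, c] = np.clip(out.data[:, c] - bg, 0.0, None)
        if not np.any(out.data[:, c] > 0):
            warnings.warn(f"channel {stack.channel_names[c]} all zero after "
                          "background subtraction")
        estimates.append(bg)
    return out, estimates


def flatfield_correct(stack: ImageStack,
                      flatfield: np.ndarray) -> ImageStack:
    """Divide every frame by the flat-field, normalized to unit mean.

    ``flatfield`` may be a measured calibration frame or a parametric
    vignette (see :func:`asterflux.synthio.parametric_vignette`); it must be
    strictly positive everywhere.
    """
    ff = np.asarray(flatfield, dtype=float)
    if ff.shape != stack.shape:
        raise ValueError("flat-field shape does not match stack frames")
    if np.any(ff <= 0):
        raise ValueError("flat-field must be strictly positive")
    ff = ff / ff.mean()
    out = stack.copy()
    out.data = out.data / ff
    return out


def outside_aster_mask(shape: tuple[int, int], pixel_size: float,
                       center: tuple[float, float], R_t: float,
                       annulus: tuple[float, float] = (10.0, 30.0),
                       ) -> np.ndarray:
    """Mask of the outside-aster reference annulus R+10..R+30 µm.

    The inner offset skips the peripheral depletion band; the annulus is
    clipped to the image.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    rr = np.hypot(xx * pixel_size - center[0], yy * pixel_size - center[1])
    return (rr >= R_t + annulus[0]) & (rr <= R_t + annulus[1])


def normalize_bleach(stack: ImageStack, mode: str = "roi_total",
                     roi: Roi | None = None,
                     R: AsterRadiusTable | None = None,
                     center_traj=None, channel: int | str = 0,
                     annulus: tuple[float, float] = (10.0, 30.0),
                     ) -> tuple[ImageStack, np.ndarray]:
    """Rescale frames so a conserved reference statistic is constant.

    ``mode='roi_total'``: the summed intensity of ``channel`` inside ``roi``
    (default: whole frame) is held at its first-frame value.
    ``mode='outside_aster'``: the mean of ``channel`` in the annulus from
    R(t)+10 to R(t)+30 µm about ``center_traj`` is held constant.

    Returns the normalized stack and the per-frame scale factors; scaling
    is applied to all channels (bleaching is an illumination effect).
    """
    c = stack.channel_index(channel)
    refs = np.empty(stack.n_frames)
    if mode == "roi_total":
        mask = roi.mask if roi is not None else np.ones(stack.shape, bool)
        for k in range(stack.n_frames):
            refs[k] = stack.data[k, c][mask].sum()
    elif mode == "outside_aster":
        if R is None or center_traj is None:
            raise ValueError("outside_aster mode needs R table and center")
        for k, t in enumerate(stack.times):
            ctr = center_traj.interp(t)
            m = outside_aster_mask(stack.shape, stack.pixel_size,
                                   (ctr[0], ctr[1]), float(R(t)), annulus)
            refs[k] = stack.data[k, c][m].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(refs <= 0):
        raise ValueError("reference statistic is non-positive in some frame")
    scales = refs[0] / refs
    out = stack.copy()
    out.data = out.data * scales[:, None, None, None]
    return out, scales


def preprocess(stack: ImageStack, flatfield: np.ndarray | None = None,
               background: str = "percentile", background_value: float = 1.0,
               bleach_mode: str | None = "roi_total", roi: Roi | None = None,
               R: AsterRadiusTable | None = None, center_traj=None,
               channel: int | str = 0):
    """The documented pipeline: subtract -> flat-field -> normalize.

    Returns ``(stack, log)`` where ``log`` records the background estimates
    and bleach scale factors.
    """
    out, bgs = subtract_background(stack, background, background_value)
    if flatfield is not None:
        out = flatfield_correct(out, flatfield)
    scales = np.ones(stack.n_frames)
    if bleach_mode is not None:
        out, scales = normalize_bleach(out, bleach_mode, roi=roi, R=R,
                                       center_traj=center_traj,
                                       channel=channel)
    return out, {"background": bgs, "bleach_scales": scales}
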