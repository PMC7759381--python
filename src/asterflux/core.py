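"""Shared data containers for calibrated time-lapse analysis.

All positions and lengths are in micrometres, times in seconds, velocities in
µm/s unless a field name says otherwise (e.g. separation speeds are reported
in µm/min, matching how aster separation rates are usually quoted).

Image convention: ``data`` is indexed ``(frame, channel, row, col)``; the x
coordinate runs along columns and y along rows, so y increases *downward* as
in every image viewer.  Physical coordinates are ``x = col * pixel_size`` and
``y = row * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A calibrated multi-channel fluorescence time-lapse.

    Parameters
    ----------
    data:
        Float array of shape ``(n_frames, n_channels, ny, nx)``.
    pixel_size:
        µm per pixel.
    frame_interval:
        Seconds between consecutive frames.
    channel_names:
        One name per channel, e.g. ``["er", "mt"]``.
    t0_offset:
        Time of the first frame relative to the start of the experiment
        (sample perfusion / warming), in seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: list[str]
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (frame, channel, y, x)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (including ``t0_offset``)."""
        return self.t0_offset + np.arange(self.n_frames) * self.frame_interval

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """View of one channel, shape ``(n_frames, ny, nx)``."""
        return self.data[:, self.channel_index(channel)]

    def copy(self) -> "ImageStack":
        return ImageStack(
            self.data.copy(), self.pixel_size, self.frame_interval,
            list(self.channel_names), self.t0_offset,
        )

    # -- IO ---------------------------------------------------------------
    def save_tiff(self, path: str | Path) -> None:
        """Write a 16-bit ImageJ-compatible TCYX TIFF with calibration."""
        arr = np.clip(self.data, 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            str(path), arr, imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={
                "axes": "TCYX",
                "unit": "um",
                "finterval": self.frame_interval,
                "Labels": list(self.channel_names),
            },
        )

    @classmethod
    def load_tiff(cls, path: str | Path,
                  channel_names: Sequence[str] | None = None) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            meta = tf.imagej_metadata or {}
            xres = tf.pages[0].tags.get("XResolution")
            pixel_size = 1.0
            if xres is not None:
                num, den = xres.value
                if num:
                    pixel_size = den / num
            interval = float(meta.get("finterval", 1.0))
            labels = channel_names or meta.get("Labels")
        if arr.ndim == 3:  # TYX -> single channel
            arr = arr[:, None]
        if labels is None:
            labels = [f"ch{i}" for i in range(arr.shape[1])]
        return cls(arr.astype(float), pixel_size, interval, list(labels))


@dataclass
class Roi:
    """Boolean region-of-interest mask with a human-readable provenance."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class Trajectory:
    """Time-indexed particle positions in physical units.

    ``frames`` are the stack frame indices at which the particle is present
    (strictly increasing; particles may enter or leave the field of view
    mid-movie), ``t`` the corresponding times in seconds.
    """

    id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    def at_frame(self, frame: int) -> tuple[float, float] | None:
        idx = np.nonzero(self.frames == frame)[0]
        if len(idx) == 0:
            return None
        i = idx[0]
        return float(self.x[i]), float(self.y[i])

    def interp(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated (x, y) at arbitrary times."""
        x = np.interp(t, self.t, self.x)
        y = np.interp(t, self.t, self.y)
        return np.stack([x, y], axis=-1)

    def common_frames(self, other: "Trajectory") -> np.ndarray:
        return np.intersect1d(self.frames, other.frames)


def trajectories_to_frame(trajs: Sequence[Trajectory]):
    """Long-format table (id, frame, t_s, x_um, y_um, label) of trajectories."""
    import pandas as pd

    rows = []
    for tr in trajs:
        for f, t, x, y in zip(tr.frames, tr.t, tr.x, tr.y):
            rows.append((tr.id, int(f), float(t), float(x), float(y),
                         tr.label or ""))
    return pd.DataFrame(rows, columns=["id", "frame", "t_s", "x_um", "y_um",
                                       "label"])


def trajectories_from_frame(df) -> list[Trajectory]:
    out = []
    for pid, grp in df.groupby("id"):
        grp = grp.sort_values("frame")
        label = str(grp["label"].iloc[0]) if "label" in grp else None
        out.append(Trajectory(int(pid), grp["frame"].to_numpy(),
                              grp["t_s"].to_numpy(), grp["x_um"].to_numpy(),
                              grp["y_um"].to_numpy(), label or None))
    return out


@dataclass
class FlowField:
    """Gridded velocity vectors for one consecutive frame pair.

    ``x, y`` are interrogation-window centre coordinates (µm, 2-D arrays),
    ``u, v`` the velocity components (µm/s) and ``valid`` marks vectors that
    survived correlation and outlier checks.  Invalid vectors are excluded
    from every downstream statistic, never interpolated.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    window_size: int
    overlap: float
    frame_pair: tuple[int, int]
    t: float  # midpoint time of the pair, seconds

    @property
    def grid_spacing_um(self) -> float:
        if self.x.shape[1] > 1:
            return float(self.x[0, 1] - self.x[0, 0])
        return float(self.window_size)

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class ProjectedVelocityMap:
    """Velocity component along a line, binned along the line over time.

    ``s`` is the signed distance along the line (µm; origin at the reference
    point, positive toward the second anchor); ``w`` has shape
    ``(n_pairs, len(s))`` and holds the projected velocity in µm/s.
    """

    s: np.ndarray
    t: np.ndarray
    w: np.ndarray
    valid: np.ndarray
    reference: str = "none"


@dataclass
class Kymograph:
    """Position-along-a-line × time intensity matrix.

    One row per frame; ``s`` origin at the chosen reference point (midpoint
    between the two anchors, one anchor, or the lab frame).  ``annotations``
    maps a track name to its per-row s-position (e.g. the two MTOCs).
    """

    s: np.ndarray
    t: np.ndarray
    intensity: np.ndarray
    reference: str
    annotations: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class RadialProfile:
    """Mean intensity in annular bins about a (possibly moving) centre."""

    bin_centers: np.ndarray
    values: np.ndarray           # (n_frames, n_bins)
    bin_width: float
    t: np.ndarray
    normalized_outside: bool = False
    counts: np.ndarray | None = None


@dataclass
class AsterRadiusTable:
    """Aster periphery radius R(t)."""

    t: np.ndarray
    R: np.ndarray
    method: str = ""

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        good = np.isfinite(self.R)
        return np.interp(t, self.t[good], self.R[good])


@dataclass
class MassTransportMap:
    """Net inward flux of normalized fluorescence across MTOC-centred circles.

    ``flux[k, j]`` is the intensity crossing radius ``r_edges[j]`` inward
    between frames ``k`` and ``k+1``, in % of the ROI total per minute
    (positive = toward the MTOC).
    """

    r_edges: np.ndarray
    t: np.ndarray                # midpoint time of each frame pair
    flux: np.ndarray             # (n_pairs, n_edges)
    sector: tuple[float, float] | None = None
    units: str = "% of total per min"

    def peak(self) -> tuple[float, float, float]:
        """(value, radius, time) of the maximum inward flux."""
        k, j = np.unravel_index(np.nanargmax(self.flux), self.flux.shape)
        return float(self.flux[k, j]), float(self.r_edges[j]), float(self.t[k])
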