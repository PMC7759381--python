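"""Particle detection and linking, Delaunay neighbour statistics for MTOC
separation, and bead-transport analysis.

Detection is local-maxima of a Gaussian-smoothed frame refined by an
intensity-weighted centroid; linking is greedy mutual-nearest-neighbour
with no gap closing, so trajectories end when a particle leaves the field
(preserving enter/exit semantics).  Neighbour pairs are defined once, by
the Delaunay triangulation of MTOC positions at the earliest time point,
and followed over the movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from skimage.feature import peak_local_max

from .core import ImageStack, Trajectory


# ---------------------------------------------------------------------------
# detection and linking
# ---------------------------------------------------------------------------


def detect_particles(frame: np.ndarray, pixel_size: float,
                     min_intensity: float, min_sep: float = 5.0,
                     smooth_sigma_px: float = 1.5) -> np.ndarray:
    """Detect bright particles in one frame; returns (n, 2) x,y in µm.

    Local maxima of the Gaussian-smoothed frame above ``min_intensity``,
    refined by an intensity-weighted centroid in a 7x7 window; duplicate
    detections within ``min_sep`` µm are merged.
    """
    if min_sep <= 0:
        raise ValueError("min_sep must be > 0")
    sm = ndimage.gaussian_filter(np.asarray(frame, dtype=float),
                                 smooth_sigma_px)
    min_dist = max(1, int(round(min_sep / pixel_size)))
    peaks = peak_local_max(sm, min_distance=min_dist,
                           threshold_abs=min_intensity, exclude_border=False)
    if len(peaks) == 0:
        return np.empty((0, 2))
    ny, nx = frame.shape
    pts = []
    for (py, px) in peaks:
        y0, y1 = max(0, py - 3), min(ny, py + 4)
        x0, x1 = max(0, px - 3), min(nx, px + 4)
        patch = sm[y0:y1, x0:x1] - sm[y0:y1, x0:x1].min()
        tot = patch.sum()
        if tot <= 0:
            cy, cx = float(py), float(px)
        else:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((patch * yy).sum() / tot)
            cx = float((patch * xx).sum() / tot)
        pts.append((cx * pixel_size, cy * pixel_size))
    pts = np.array(pts)
    # merge near-duplicates
    keep = np.ones(len(pts), bool)
    tree = cKDTree(pts)
    for i, j in sorted(tree.query_pairs(min_sep)):
        if keep[i] and keep[j]:
            keep[j] = False
    return pts[keep]


def link_trajectories(detections: Sequence[np.ndarray], times: np.ndarray,
                      max_step: float) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    A detection links to the previous frame's trajectory only if each is
    the other's nearest neighbour and the step is below ``max_step`` µm.
    Unmatched detections open new trajectories; unmatched trajectories end
    (no gap closing).  The result is invariant to detection order within a
    frame because the mutual-NN criterion is order-free.
    """
    next_id = 1
    live: dict[int, list] = {}
    done: list[tuple[int, list]] = []
    for k, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, 2)
        if live and len(det):
            ids = list(live.keys())
            prev = np.array([live[i][-1][1:] for i in ids])
            d = np.linalg.norm(prev[:, None, :] - det[None, :, :], axis=2)
            nn_prev = d.argmin(axis=1)
            nn_det = d.argmin(axis=0)
            matched_det = set()
            still: dict[int, list] = {}
            for pi, tid in enumerate(ids):
                dj = nn_prev[pi]
                if nn_det[dj] == pi and d[pi, dj] <= max_step:
                    live[tid].append((k, det[dj, 0], det[dj, 1]))
                    still[tid] = live[tid]
                    matched_det.add(dj)
                else:
                    done.append((tid, live[tid]))
            live = still
            new = [j for j in range(len(det)) if j not in matched_det]
        else:
            done.extend(live.items())
            live = {}
            new = list(range(len(det)))
        for j in new:
            live[next_id] = [(k, det[j, 0], det[j, 1])]
            next_id += 1
    done.extend(live.items())
    trajs = []
    for tid, rows in sorted(done):
        rows = np.array(rows)
        frames = rows[:, 0].astype(int)
        trajs.append(Trajectory(tid, frames, np.asarray(times)[frames],
                                rows[:, 1], rows[:, 2]))
    return trajs


def track_stack(stack: ImageStack, channel: int | str = 0,
                min_intensity: float = 200.0, min_sep: float = 5.0,
                max_step: float = 10.0) -> list[Trajectory]:
    """Detect and link over a whole stack."""
    dets = [detect_particles(f, stack.pixel_size, min_intensity, min_sep)
            for f in stack.channel(channel)]
    return link_trajectories(dets, stack.times, max_step)


def mean_speed(traj: Trajectory) -> float:
    """Mean frame-to-frame speed (µm/s) of a trajectory."""
    if len(traj) < 2:
        return float("nan")
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float((steps / np.diff(traj.t)).mean())


# ---------------------------------------------------------------------------
# Delaunay neighbour graph and separation statistics
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    """MTOC ids with t0 positions plus frozen Delaunay edges and CPC labels."""

    nodes: dict[int, tuple[float, float]]
    edges: list[tuple[int, int]]
    cpc: dict[tuple[int, int], float]
    frame0: int


def build_neighbor_graph(trajectories: Sequence[Trajectory],
                         cpc_labels: pd.DataFrame | None = None,
                         ) -> NeighborGraph:
    """Delaunay triangulation of MTOCs at the earliest time point, frozen.

    ``cpc_labels`` has columns id_a, id_b, cpc in {0, 0.5, 1}; edges absent
    from the table default to 0 (not CPC-positive).
    """
    f0 = min(tr.frames[0] for tr in trajectories)
    present = [tr for tr in trajectories if tr.frames[0] == f0]
    if len(present) < 3:
        raise ValueError("need >= 3 MTOCs at the earliest time point")
    pts = np.array([[tr.x[0], tr.y[0]] for tr in present])
    ids = [tr.id for tr in present]
    if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        raise ValueError("collinear MTOC positions: triangulation impossible")
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i, j in combinations(simplex, 2):
            a, b = sorted((ids[i], ids[j]))
            edges.add((a, b))
    labels: dict[tuple[int, int], float] = {e: 0.0 for e in edges}
    if cpc_labels is not None:
        for _, row in cpc_labels.iterrows():
            key = tuple(sorted((int(row["id_a"]), int(row["id_b"]))))
            if key in labels:
                labels[key] = float(row["cpc"])
    nodes = {tr.id: (float(tr.x[0]), float(tr.y[0])) for tr in present}
    return NeighborGraph(nodes, sorted(edges), labels, int(f0))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x
    kernel = np.ones(window) / window
    sm = np.convolve(x, kernel, mode="same")
    # fix the edges (partial windows)
    half = window // 2
    for i in range(half):
        sm[i] = x[:i + half + 1].mean()
        sm[-(i + 1)] = x[-(i + half + 1):].mean()
    return sm


def edge_separation_speed(trajA: Trajectory, trajB: Trajectory,
                          smooth_window: int = 3):
    """d0, the separation-speed series (µm/min) and the common times."""
    common = trajA.common_frames(trajB)
    if len(common) < 3:
        return None
    ia = np.searchsorted(trajA.frames, common)
    ib = np.searchsorted(trajB.frames, common)
    d = np.hypot(trajA.x[ia] - trajB.x[ib], trajA.y[ia] - trajB.y[ib])
    t = trajA.t[ia]
    d_s = _moving_average(d, smooth_window)
    speed = np.gradient(d_s, t) * 60.0   # central differences, µm/min
    return float(d[0]), speed, t


def separation_analysis(graph: NeighborGraph,
                        trajectories: Sequence[Trajectory],
                        smooth_window: int = 3,
                        cpc_positive_min: float = 0.5):
    """Maximum separation speed vs initial distance, with a linear fit.

    Per Delaunay edge: the pairwise distance on common frames is smoothed by
    a centred moving average, differentiated by central differences, and the
    maximum (µm/min) reported against d0.  A least-squares line is fitted
    over the CPC-positive edges (label >= ``cpc_positive_min``) when at
    least three are available.

    Returns ``(table, fit)`` where ``table`` has one row per edge and
    ``fit`` is ``{"slope", "intercept", "r"}`` or None.
    """
    by_id = {tr.id: tr for tr in trajectories}
    rows = []
    for (a, b) in graph.edges:
        res = edge_separation_speed(by_id[a], by_id[b], smooth_window)
        if res is None:
            warnings.warn(f"edge ({a},{b}) has < 3 common frames; dropped")
            continue
        d0, speed, _ = res
        rows.append({"id_a": a, "id_b": b, "d0_um": d0,
                     "max_speed_um_min": float(speed.max()),
                     "cpc": graph.cpc.get((a, b), 0.0)})
    table = pd.DataFrame(rows)
    fit = None
    pos = table[table["cpc"] >= cpc_positive_min]
    if len(pos) >= 3:
        slope, intercept = np.polyfit(pos["d0_um"], pos["max_speed_um_min"], 1)
        r = float(np.corrcoef(pos["d0_um"], pos["max_speed_um_min"])[0, 1])
        fit = {"slope": float(slope), "intercept": float(intercept), "r": r}
    return table, fit


# ---------------------------------------------------------------------------
# bead transport
# ---------------------------------------------------------------------------


def aster_entry_time(bead: Trajectory, mtoc: Trajectory,
                     R: Callable[[float], float]) -> float | None:
    """Earliest common time at which |bead - MTOC| <= R(t); None if never."""
    common = bead.common_frames(mtoc)
    if len(common) == 0:
        raise ValueError("bead and MTOC share no frames")
    ib = np.searchsorted(bead.frames, common)
    im = np.searchsorted(mtoc.frames, common)
    d = np.hypot(bead.x[ib] - mtoc.x[im], bead.y[ib] - mtoc.y[im])
    t = bead.t[ib]
    inside = d <= np.asarray(R(t), dtype=float)
    if not inside.any():
        return None
    return float(t[np.argmax(inside)])


def bead_velocity_distribution(beads: Sequence[Trajectory], mtoc: Trajectory,
                               entry_times: dict[int, float],
                               stop_radius: float = 3.0):
    """Pooled inward radial speed of beads after aster entry.

    Per bead, the radial distance to the MTOC is differentiated over the
    frames from entry until the bead first comes within ``stop_radius`` of
    the MTOC (beads park at the MTOC; later frames would dilute the
    estimate).  Sign convention: positive = inward.  Returns a dict with
    the pooled mean, SD, per-bead means and all pooled samples (µm/s).
    """
    samples = []
    per_bead = {}
    for bead in beads:
        te = entry_times.get(bead.id)
        if te is None:
            continue
        common = bead.common_frames(mtoc)
        ib = np.searchsorted(bead.frames, common)
        im = np.searchsorted(mtoc.frames, common)
        d = np.hypot(bead.x[ib] - mtoc.x[im], bead.y[ib] - mtoc.y[im])
        t = bead.t[ib]
        sel = t >= te
        if sel.sum() < 2:
            continue
        d, t = d[sel], t[sel]
        arrived = np.nonzero(d <= stop_radius)[0]
        if len(arrived):
            end = arrived[0] + 1
            d, t = d[:end], t[:end]
        if len(d) < 2:
            continue
        v = -np.diff(d) / np.diff(t)       # positive inward
        samples.append(v)
        per_bead[bead.id] = float(v.mean())
    if not samples:
        raise ValueError("no bead has post-entry samples")
    pooled = np.concatenate(samples)
    return {"mean": float(pooled.mean()), "sd": float(pooled.std(ddof=1)),
            "per_bead": per_bead, "samples": pooled}


# ---------------------------------------------------------------------------
# brute-force Delaunay oracle (for validation only)
# ---------------------------------------------------------------------------


def delaunay_edges_bruteforce(points: np.ndarray) -> set[tuple[int, int]]:
    """Edges of the Delaunay triangulation by the empty-circumcircle test.

    O(n^4); intended as an independent oracle on <= 12 points in general
    position.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) *
              (cy - ay) + (cx ** 2 + cy ** 2) * (ay - by)) / d
        uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) *
              (ax - cx) + (cx ** 2 + cy ** 2) * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 < r2 - 1e-9:
                empty = False
                break
        if empty:
            edges.update({tuple(sorted(p)) for p in
                          ((i, j), (j, k), (i, k))})
    return edges
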