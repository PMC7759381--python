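"""Detection/linking, Delaunay separation statistics, bead transport."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asterflux.core import Trajectory
from asterflux.synthio import render_spots
from asterflux.tracking import (aster_entry_time, bead_velocity_distribution,
                                build_neighbor_graph,
                                delaunay_edges_bruteforce, detect_particles,
                                edge_separation_speed, link_trajectories,
                                mean_speed, separation_analysis)
from conftest import static_trajectory


class TestDetection:
    def test_blank_frame_no_detections(self):
        out = detect_particles(np.zeros((64, 64)), 1.0, min_intensity=10.0)
        assert len(out) == 0

    def test_two_spots_localized_within_half_pixel(self):
        """Two rendered particles 40 µm apart, each found within 0.5 px."""
        truth = [(20.3, 30.7), (60.3, 30.7)]
        frame = np.zeros((96, 96))
        for (x, y) in truth:
            frame += render_spots((96, 96), 1.0, [x], [y], 500.0, 1.5)
        found = detect_particles(frame, 1.0, min_intensity=100.0, min_sep=5.0)
        assert len(found) == 2
        found = found[np.argsort(found[:, 0])]
        for (fx, fy), (tx, ty) in zip(found, truth):
            assert abs(fx - tx) < 0.5 and abs(fy - ty) < 0.5

    def test_full_field_recall(self, rng):
        """12 well-separated bright MTOCs: 12 detections, recall 1.0."""
        pts = np.stack([rng.uniform(15, 240, 12), rng.uniform(15, 240, 12)],
                       axis=1)
        # enforce separation
        keep = []
        for p in pts:
            if all(np.hypot(*(p - q)) > 25 for q in keep):
                keep.append(p)
        frame = 100.0 + rng.normal(0, 10, (256, 256))
        for (x, y) in keep:
            frame += render_spots((256, 256), 1.0, [x], [y], 800.0, 1.5)
        found = detect_particles(frame, 1.0, min_intensity=250.0, min_sep=5.0)
        assert len(found) == len(keep)


class TestLinking:
    def test_single_static_particle_spans_movie(self):
        dets = [np.array([[10.0, 12.0]])] * 8
        trajs = link_trajectories(dets, np.arange(8.0), max_step=2.0)
        assert len(trajs) == 1 and len(trajs[0]) == 8

    def test_crossing_particles_keep_identity(self):
        """Two particles pass at closest approach > max_step: mutual-NN
        linking preserves both identities."""
        t = np.arange(11.0)
        ax = np.linspace(0, 50, 11)
        ay = np.full(11, 20.0)
        bx = np.linspace(50, 0, 11)
        by = np.full(11, 40.0)          # 20 µm apart at crossing
        dets = [np.array([[ax[k], ay[k]], [bx[k], by[k]]]) for k in range(11)]
        trajs = link_trajectories(dets, t, max_step=8.0)
        assert len(trajs) == 2
        for tr in trajs:
            assert np.ptp(tr.y) < 1e-9       # each stayed in its lane

    def test_exit_mid_movie_ends_trajectory(self):
        """A particle present only in frames 0..5 of 10 yields a 6-frame
        trajectory (no gap closing)."""
        dets = [np.array([[5.0, 5.0]]) if k < 6 else np.empty((0, 2))
                for k in range(10)]
        trajs = link_trajectories(dets, np.arange(10.0), max_step=2.0)
        assert len(trajs) == 1
        np.testing.assert_array_equal(trajs[0].frames, np.arange(6))

    def test_order_invariance_within_frame(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        steps = rng.normal(0, 1.0, (6, 5, 2)).cumsum(axis=0)
        paths = pts[None] + steps
        dets_fwd = [paths[k] for k in range(6)]
        dets_rev = [paths[k][::-1].copy() for k in range(6)]
        t1 = link_trajectories(dets_fwd, np.arange(6.0), max_step=10.0)
        t2 = link_trajectories(dets_rev, np.arange(6.0), max_step=10.0)
        set1 = {tuple(np.round(np.c_[tr.x, tr.y].ravel(), 9)) for tr in t1}
        set2 = {tuple(np.round(np.c_[tr.x, tr.y].ravel(), 9)) for tr in t2}
        assert set1 == set2


def _static_trajs(points, n_frames=5):
    return [static_trajectory(x, y, n_frames, 1.0, pid=i)
            for i, (x, y) in enumerate(points)]


class TestNeighborGraph:
    def test_triangle_has_three_edges(self):
        g = build_neighbor_graph(_static_trajs([(0, 0), (10, 0), (5, 8)]))
        assert len(g.edges) == 3

    def test_convex_quad_has_five_edges(self):
        g = build_neighbor_graph(_static_trajs([(0, 0), (10, 0), (10, 10),
                                                (0, 10)]))
        assert len(g.edges) == 5

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            build_neighbor_graph(_static_trajs([(0, 0), (5, 0), (10, 0)]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_matches_bruteforce_circumcircle_oracle(self, seed, n):
        """scipy Delaunay edges equal the O(n^4) empty-circumcircle oracle
        on random general-position point sets of up to 12 points."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (n, 2))
        g = build_neighbor_graph(_static_trajs(pts))
        oracle = delaunay_edges_bruteforce(pts)
        assert set(g.edges) == oracle


class TestSeparation:
    def test_static_field_zero_speeds(self):
        pts = [(0, 0), (50, 0), (25, 40), (80, 60)]
        g = build_neighbor_graph(_static_trajs(pts, 8))
        table, fit = separation_analysis(g, _static_trajs(pts, 8))
        np.testing.assert_allclose(table["max_speed_um_min"], 0.0,
                                   atol=1e-12)

    def test_constant_recession_speed_recovered(self):
        """One pair receding at 4 µm/min: max separation speed within 2%."""
        t = np.arange(10) * 60.0
        a = Trajectory(0, np.arange(10), t, 0.0 - 2.0 / 60 * t,
                       np.zeros(10))
        b = Trajectory(1, np.arange(10), t, 100.0 + 2.0 / 60 * t,
                       np.zeros(10))
        d0, speed, _ = edge_separation_speed(a, b, smooth_window=3)
        assert d0 == pytest.approx(100.0)
        assert speed.max() == pytest.approx(4.0, rel=0.02)

    def test_time_reversal_negates_speeds(self):
        rng = np.random.default_rng(3)
        t = np.arange(12) * 30.0
        xa = np.cumsum(rng.normal(0.5, 0.3, 12))
        a = Trajectory(0, np.arange(12), t, xa, np.zeros(12))
        b = Trajectory(1, np.arange(12), t, -xa, np.zeros(12))
        _, speed, _ = edge_separation_speed(a, b, smooth_window=1)
        ar = Trajectory(0, np.arange(12), t, xa[::-1].copy(), np.zeros(12))
        br = Trajectory(1, np.arange(12), t, -xa[::-1].copy(), np.zeros(12))
        _, speed_r, _ = edge_separation_speed(ar, br, smooth_window=1)
        np.testing.assert_allclose(speed_r, -speed[::-1], atol=1e-9)

    def test_recovers_injected_negative_slope(self):
        """Generator field with slope -0.05, intercept 8, jitter 0.3 µm:
        fitted slope negative and within 20% of -0.05."""
        from asterflux.scenarios import (make_separation_field,
                                         measure_separation_fit)
        trajs, labels = make_separation_field(seed=11)
        fit = measure_separation_fit(trajs, labels)["fit"]
        assert fit["slope"] < 0
        assert abs(fit["slope"] - (-0.05)) / 0.05 < 0.20
        assert fit["r"] < -0.9


class TestBeads:
    def test_entry_time_from_crossing(self):
        n = 40
        mtoc = static_trajectory(0.0, 0.0, n, 10.0)
        bead = static_trajectory(100.0, 0.0, n, 10.0, pid=1)
        R = lambda t: 25.0 / 60.0 * np.asarray(t)
        te = aster_entry_time(bead, mtoc, R)
        assert te == pytest.approx(240.0, abs=10.0)

    def test_bead_at_mtoc_from_start(self):
        mtoc = static_trajectory(0.0, 0.0, 5, 10.0)
        bead = static_trajectory(0.5, 0.0, 5, 10.0, pid=1)
        te = aster_entry_time(bead, mtoc, lambda t: 1.0 + 0 * np.asarray(t))
        assert te == 0.0

    def test_never_inside_returns_none(self):
        mtoc = static_trajectory(0.0, 0.0, 5, 10.0)
        bead = static_trajectory(500.0, 0.0, 5, 10.0, pid=1)
        te = aster_entry_time(bead, mtoc, lambda t: np.minimum(
            np.asarray(t, float) * 0.1, 40.0))
        assert te is None

    def test_static_beads_mean_zero(self):
        mtoc = static_trajectory(0.0, 0.0, 20, 10.0)
        beads = [static_trajectory(30.0, 0.0, 20, 10.0, pid=1)]
        out = bead_velocity_distribution(beads, mtoc, {1: 0.0},
                                         stop_radius=3.0)
        assert out["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_estimator_unbiased_on_jittered_tracks(self):
        """Constant-velocity tracks with 0.5 µm jitter over 30 frames:
        pooled-mean bias < 2%."""
        rng = np.random.default_rng(9)
        n, dt, v = 30, 10.0, 0.3
        t = np.arange(n) * dt
        mtoc = static_trajectory(0.0, 0.0, n, dt)
        beads = []
        for i in range(25):
            r = 120.0 - v * t + rng.normal(0, 0.5, n)
            ang = rng.uniform(0, 2 * np.pi)
            beads.append(Trajectory(i + 1, np.arange(n), t,
                                    r * np.cos(ang), r * np.sin(ang)))
        out = bead_velocity_distribution(beads, mtoc,
                                         {b.id: 0.0 for b in beads},
                                         stop_radius=3.0)
        assert abs(out["mean"] - v) / v < 0.02


def test_mean_speed_of_circular_track():
    t = np.arange(50) * 2.0
    R, vtrue = 12.5, 1.0
    om = vtrue / R
    tr = Trajectory(0, np.arange(50), t, R * np.cos(om * t),
                    R * np.sin(om * t))
    # chord/arc correction is ~0.1% at this sampling
    assert mean_speed(tr) == pytest.approx(vtrue, rel=0.005)
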