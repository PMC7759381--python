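"""Generator-level guarantees: determinism, closed-form cloud widths,
advection fidelity, conservation, and scene kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asterflux.synthio import (AsterModel, ChannelSpec, CloudModel,
                               bandlimited_texture,
                               make_aster_scene, make_bead_scene,
                               make_cloud_sequence, make_mtoc_field,
                               render_spots, tukey_band, warp_backward)
from conftest import make_params


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = make_params(noise_sd=10.0, n_frames=3)
        model = AsterModel(growth_rate=25.0)
        ch = [ChannelSpec("a", advected=True, turnover_tau=60.0)]
        s1, _ = make_aster_scene(p, model, ch)
        s2, _ = make_aster_scene(p, model, ch)
        assert np.array_equal(s1.data, s2.data)

    def test_different_seed_differs(self):
        p1 = make_params(noise_sd=10.0)
        p2 = make_params(noise_sd=10.0, seed=1)
        model = AsterModel()
        ch = [ChannelSpec("a")]
        s1, _ = make_aster_scene(p1, model, ch)
        s2, _ = make_aster_scene(p2, model, ch)
        assert not np.array_equal(s1.data, s2.data)


class TestStaticScene:
    def test_no_dynamics_frames_identical(self):
        """No noise, no bleach, no flow, turnover off: frames bit-equal."""
        p = make_params(n_frames=5)
        model = AsterModel(growth_rate=0.0)
        stack, _ = make_aster_scene(p, model, [ChannelSpec("a")])
        for k in range(1, 5):
            assert np.array_equal(stack.data[k], stack.data[0])


class TestAdvection:
    def test_rigid_translation_matches_array_shift(self):
        """Uniform 3 px/frame flow: frame equals the shifted previous frame
        in the interior away from boundary inflow."""
        rng = np.random.default_rng(3)
        tex = bandlimited_texture(rng, (128, 128), 1000.0, 0.2)
        u = np.full(tex.shape, 3.0)
        v = np.zeros(tex.shape)
        warped = warp_backward(tex, u, v, fill=tex)
        np.testing.assert_allclose(warped[10:-10, 10:-10],
                                   np.roll(tex, 3, axis=1)[10:-10, 10:-10],
                                   rtol=0, atol=1e-9)

    def test_intensity_conserved_under_band_flow(self):
        """Total intensity conserved to <1% per frame for sub-2px/frame
        flows with noise, bleach, flat-field and turnover disabled."""
        p = make_params(image_shape=(256, 256), n_frames=5)
        model = AsterModel(growth_rate=25.0, v_peripheral=-0.12,
                           band_width=50.0)
        stack, _ = make_aster_scene(p, model,
                                    [ChannelSpec("a", advected=True)])
        totals = stack.data[:, 0].sum(axis=(1, 2))
        rel = np.abs(np.diff(totals)) / totals[:-1]
        assert np.all(rel < 0.01)

    def test_ground_truth_velocity_profile(self):
        """GroundTruth radial velocity equals the prescribed piecewise
        profile: plateau -0.25 µm/s at the band centre, 0 far away."""
        p = make_params(image_shape=(256, 256))
        model = AsterModel(growth_rate=25.0, v_peripheral=-0.25,
                           band_width=50.0, band_taper=0.5)
        _, gt = make_aster_scene(p, model, [ChannelSpec("a")])
        t = 240.0
        R = float(model.R(t))
        r = np.array([R - 40, R - 12, R, R + 12, R + 40])
        v = gt.velocity_profile(r, t)
        np.testing.assert_allclose(v, [0, -0.25, -0.25, -0.25, 0], atol=1e-12)

    def test_flow_field_evaluates_at_pixels(self):
        p = make_params(image_shape=(64, 64))
        model = AsterModel(growth_rate=25.0, v_peripheral=-0.2)
        _, gt = make_aster_scene(p, model, [ChannelSpec("a")])
        U, V = gt.flow_field(2)
        assert U.shape == (64, 64) and np.all(np.isfinite(U))
        # velocity points along the radial direction
        cx, cy = p.center_um
        yy, xx = np.mgrid[0:64, 0:64] * p.pixel_size
        cross = U * (yy - cy) - V * (xx - cx)
        np.testing.assert_allclose(cross, 0, atol=1e-9)


class TestCloudSequence:
    def test_sigma_sq_closed_form(self):
        """sigma^2(t) = sigma0^2 + 2 D t: 4, 204, ..., 1004 µm² at D=100."""
        p = make_params(image_shape=(64, 64), pixel_size=0.32,
                        frame_interval=1.0, n_frames=6)
        cloud = CloudModel(D=100.0, sigma0=2.0, amplitude=10.0)
        _, gt = make_cloud_sequence(p, cloud)
        np.testing.assert_allclose(gt.sigma_sq,
                                   [4, 204, 404, 604, 804, 1004])

    def test_frozen_cloud_without_diffusion(self):
        """D -> 0, no drift: centre and width constant over frames."""
        p = make_params(image_shape=(96, 96), pixel_size=0.32,
                        frame_interval=1.0, n_frames=4)
        cloud = CloudModel(D=1e-9, sigma0=4.0, amplitude=50.0,
                           mtoc_amplitude=0.0)
        stack, gt = make_cloud_sequence(p, cloud)
        assert np.ptp(gt.sigma_sq) < 1e-6
        assert np.allclose(gt.cloud_centers, gt.cloud_centers[0])
        for k in range(1, 4):
            np.testing.assert_allclose(stack.data[k], stack.data[0])

    def test_rendered_second_moment_matches_analytic(self):
        """Second moment of the noiseless rendered cloud equals sigma^2(t)
        within 0.5% (field large enough that tails are unclipped)."""
        p = make_params(image_shape=(768, 768), pixel_size=0.32,
                        frame_interval=1.0, n_frames=4)
        cloud = CloudModel(D=100.0, sigma0=2.0, amplitude=10.0,
                           mtoc_amplitude=0.0)
        stack, gt = make_cloud_sequence(p, cloud)
        yy, xx = np.mgrid[0:768, 0:768] * p.pixel_size
        for k in range(4):
            img = stack.data[k, 0]
            tot = img.sum()
            cx = (img * xx).sum() / tot
            cy = (img * yy).sum() / tot
            m2 = (img * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum() / tot / 2
            assert abs(m2 - gt.sigma_sq[k]) / gt.sigma_sq[k] < 0.005

    def test_pre_release_frames_are_background_only(self):
        p = make_params(image_shape=(64, 64), pixel_size=0.32,
                        frame_interval=1.0, n_frames=5,
                        background_offset=7.0)
        cloud = CloudModel(release_time=2.0, D=50.0, sigma0=2.0,
                           amplitude=30.0, mtoc_amplitude=0.0)
        stack, _ = make_cloud_sequence(p, cloud)
        np.testing.assert_allclose(stack.data[0, 0], 7.0)
        assert stack.data[2, 0].max() > 7.0 + 1.0


class TestMtocField:
    def test_static_field(self):
        trajs, _ = make_mtoc_field(8, speed_model=(0.0, 0.0), jitter_sd=0.0,
                                   seed=1)
        for tr in trajs:
            assert np.ptp(tr.x) == 0 and np.ptp(tr.y) == 0

    def test_pair_recedes_at_prescribed_speed(self):
        """intercept 4 µm/min, slope 0: pair distance grows 4 µm/min."""
        trajs, labels = make_mtoc_field(4, speed_model=(0.0, 4.0),
                                        jitter_sd=0.0, seed=2)
        a, b = trajs[0], trajs[1]
        d = np.hypot(a.x - b.x, a.y - b.y)
        rate = np.diff(d) / np.diff(a.t) * 60.0
        np.testing.assert_allclose(rate, 4.0, rtol=1e-9)
        assert labels.iloc[0]["cpc"] == 1.0

    def test_rejects_too_few(self):
        with pytest.raises(ValueError):
            make_mtoc_field(2)


class TestBeadScene:
    def test_entry_time_from_growth_crossing(self):
        """Growth 25 µm/min, bead at 100 µm: true entry at 240 s."""
        p = make_params(image_shape=(384, 384), n_frames=30,
                        frame_interval=10.0)
        model = AsterModel(growth_rate=25.0)
        _, gt = make_bead_scene(p, model, bead_speed_inside=0.0, n_beads=1,
                                bead_radii=(100.0, 100.0), jitter_sd=0.0)
        assert gt.entry_times[1] == pytest.approx(240.0)

    def test_static_beads_never_move(self):
        p = make_params(image_shape=(256, 256), n_frames=8)
        model = AsterModel(growth_rate=25.0)
        _, gt = make_bead_scene(p, model, bead_speed_inside=0.0, n_beads=3,
                                bead_radii=(50.0, 70.0), jitter_sd=0.0)
        for tr in gt.trajectories[1:]:
            assert np.ptp(tr.x) < 1e-9 and np.ptp(tr.y) < 1e-9

    def test_negative_speed_rejected(self):
        p = make_params()
        with pytest.raises(ValueError):
            make_bead_scene(p, AsterModel(), bead_speed_inside=-0.1,
                            n_beads=1)


class TestFluxCalibration:
    def test_ground_truth_peak_hits_target(self):
        """The particle weight solves the calibration equation exactly."""
        p = make_params(image_shape=(256, 256), n_frames=12,
                        frame_interval=10.0)
        model = AsterModel(growth_rate=25.0, v_peripheral=-0.25,
                           band_width=50.0)
        _, gt = make_aster_scene(p, model, [
            ChannelSpec("org", texture_contrast=0.1, n_particles=6000,
                        target_peak_flux=1.5)])
        assert np.nanmax(gt.flux_map.flux) == pytest.approx(1.5, rel=1e-9)

    def test_analytic_flux_agrees_at_band_peak(self):
        """Particle-crossing flux matches rho*v*2*pi*r at the peak cell
        (undisturbed density ahead of the outward-sweeping band)."""
        p = make_params(image_shape=(256, 256), n_frames=12,
                        frame_interval=10.0)
        model = AsterModel(growth_rate=25.0, v_peripheral=-0.25,
                           band_width=50.0)
        _, gt = make_aster_scene(p, model, [
            ChannelSpec("org", texture_contrast=0.1, n_particles=40000,
                        target_peak_flux=1.5)])
        k, j = np.unravel_index(np.nanargmax(gt.flux_map.flux),
                                gt.flux_map.flux.shape)
        measured = gt.flux_map.flux[k, j]
        analytic = gt.analytic_flux.flux[k, j]
        assert abs(measured - analytic) / analytic < 0.15


class TestRenderSpots:
    def test_sum_normalization_conserves_total(self):
        img = render_spots((64, 64), 1.0, [32.0], [32.0], 500.0, 1.5,
                           normalize="sum")
        assert img.sum() == pytest.approx(500.0, rel=1e-6)

    def test_peak_normalization(self):
        img = render_spots((64, 64), 1.0, [32.0], [32.0], 100.0, 1.5)
        assert img.max() == pytest.approx(100.0, rel=1e-6)


@settings(max_examples=30, deadline=None)
@given(center=st.floats(20, 200), width=st.floats(5, 80),
       taper=st.floats(0.05, 1.0))
def test_tukey_band_bounds_and_support(center, width, taper):
    r = np.linspace(0, 300, 1201)
    b = tukey_band(r, center, width, taper)
    assert np.all((b >= 0) & (b <= 1.0 + 1e-12))
    assert np.all(b[np.abs(r - center) > width / 2 + 1e-9] == 0)
    assert tukey_band(np.array([center]), center, width, taper)[0] == \
        pytest.approx(1.0, abs=1e-9)
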