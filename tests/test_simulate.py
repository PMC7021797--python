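"""Statistical and structural checks on the synthetic-data generator."""

import numpy as np
import pytest

from llstorm import (
    AcquisitionGeometry,
    SceneSpec,
    render_frame,
    sample_membrane_emitters,
    simulate_blinking,
    simulate_frap,
    simulate_scan_acquisition,
    simulate_trajectories,
)
from llstorm.frap import recovery_model


def single_cell_scene(**kw):
    """Two cells far apart (no contact wall, no interface)."""
    kw.setdefault("center_separation_um", 40.0)
    return SceneSpec(**kw)


class TestMembraneSampling:
    def test_zero_density_gives_zero_emitters(self):
        scene = SceneSpec(rho_basal=0, rho_apical=0, rho_interface=0)
        assert len(sample_membrane_emitters(scene, 0)) == 0

    def test_basal_disc_count_is_poisson_with_configured_mean(self):
        # R=3, h=0.59 µm → basal disc area πa², a² = R² − (R−h)²;
        # two separated cells → expected mean 2·ρ·πa² ≈ 2000 at ρ=100
        R, h, rho = 3.0, 0.59, 100.0
        a2 = R**2 - (R - h) ** 2
        expect = 2 * rho * np.pi * a2
        scene = single_cell_scene(cap_radius_um=R, cap_height_um=h,
                                  rho_basal=rho, rho_apical=0, rho_interface=0)
        counts = [len(sample_membrane_emitters(scene, s)) for s in range(200)]
        tol = 3 * np.sqrt(expect / 200)
        assert abs(np.mean(counts) - expect) < tol

    def test_doubling_interface_density_doubles_interface_count(self):
        base = dict(rho_basal=0, rho_apical=50.0)
        n1 = [np.sum(sample_membrane_emitters(
            SceneSpec(rho_interface=50.0, **base), s).labels == "interface")
            for s in range(60)]
        n2 = [np.sum(sample_membrane_emitters(
            SceneSpec(rho_interface=100.0, **base), 1000 + s).labels == "interface")
            for s in range(60)]
        ratio = np.mean(n2) / np.mean(n1)
        se = ratio * np.sqrt(1 / np.sum(n1) + 1 / np.sum(n2))
        assert abs(ratio - 2.0) < 4 * se

    def test_emitters_lie_on_the_membrane(self):
        scene = SceneSpec(rho_basal=20, rho_apical=20, rho_interface=20)
        truth = sample_membrane_emitters(scene, 3)
        R = scene.cap_radius_um * 1000
        zc = (scene.cap_height_um - scene.cap_radius_um) * 1000
        ymid = scene.center_y_um * 1000
        sep = scene.center_separation_um * 1000
        centers = np.array([[0.0, ymid - sep / 2, zc], [0.0, ymid + sep / 2, zc]])
        wall_r = np.sqrt(R**2 - (sep / 2) ** 2)
        P = truth.positions
        assert (P[:, 2] >= -1e-9).all()
        on_sphere = np.minimum(
            np.abs(np.linalg.norm(P - centers[0], axis=1) - R),
            np.abs(np.linalg.norm(P - centers[1], axis=1) - R),
        )
        on_basal = np.abs(P[:, 2])
        on_wall = np.where(
            np.hypot(P[:, 0], P[:, 2] - zc) <= wall_r,
            np.abs(P[:, 1] - ymid), np.inf,
        )
        assert (np.minimum(np.minimum(on_sphere, on_basal), on_wall) < 1.0).all()
        assert set(np.unique(truth.labels)) <= {"basal", "apical", "interface"}

    def test_reproducible_given_seed(self):
        scene = SceneSpec()
        a = sample_membrane_emitters(scene, 42)
        b = sample_membrane_emitters(scene, 42)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestBlinking:
    def test_zero_activation_rate_means_all_frames_empty(self):
        active = simulate_blinking(100, 50, activation_rate=0.0, seed=0)
        assert all(len(a) == 0 for a in active)

    def test_mean_on_time_matches_geometric_mean(self):
        n = 10_000
        active = simulate_blinking(n, 200, mean_on_frames=3.0,
                                   activation_rate=0.5, seed=7)
        on = np.zeros(n, int)
        last_frame = np.full(n, -1)
        for f, idx in enumerate(active):
            on[idx] += 1
            last_frame[idx] = f
        complete = last_frame < 199          # exclude runs truncated by the movie
        durations = on[(on > 0) & complete]
        assert len(durations) > 9000
        assert abs(durations.mean() - 3.0) < 0.05 * 3.0

    def test_immortal_emitter_active_in_every_frame(self):
        active = simulate_blinking(1, 30, mean_on_frames=np.inf,
                                   activation_rate=1.0, seed=0)
        assert all(list(a) == [0] for a in active)


class TestRenderFrame:
    def test_no_emitters_gives_constant_offset_frame(self, calibration):
        scene = SceneSpec(background=0.0, camera_offset=100.0)
        geo = AcquisitionGeometry()
        frame = render_frame(np.empty((0, 3)), geo, calibration, scene, (16, 16))
        np.testing.assert_array_equal(frame, np.full((16, 16), 100.0))

    def test_integrated_photons_match_analytic_gaussian_mass(self, calibration):
        scene = SceneSpec(background=0.0, camera_offset=0.0, mean_photons=2000.0)
        geo = AcquisitionGeometry()
        pos = np.array([[16 * geo.pixel_size, 16 * geo.pixel_size, 0.0]])
        frame = render_frame(pos, geo, calibration, scene, (33, 33))
        assert abs(frame.sum() - 2000.0) < 0.005 * 2000.0

    def test_astigmatic_anisotropy_flips_sign_with_depth(self, calibration):
        scene = SceneSpec(background=0.0, camera_offset=0.0)
        geo = AcquisitionGeometry()
        c = 16 * geo.pixel_size
        ii = np.arange(33)

        def moment_diff(z):
            img = render_frame([[c, c, z]], geo, calibration, scene, (33, 33))
            tot = img.sum()
            mx = ((ii - 16) ** 2 * img.sum(axis=0)).sum() / tot
            my = ((ii - 16) ** 2 * img.sum(axis=1)).sum() / tot
            return mx - my

        assert moment_diff(+400.0) * moment_diff(-400.0) < 0

    def test_emitter_outside_calibration_range_is_skipped(self, calibration):
        scene = SceneSpec(background=0.0, camera_offset=0.0)
        geo = AcquisitionGeometry()
        c = 16 * geo.pixel_size
        frame = render_frame([[c, c, 5000.0]], geo, calibration, scene, (33, 33))
        assert frame.sum() == 0.0


class TestScanAcquisition:
    @staticmethod
    def small():
        scene = SceneSpec(cap_radius_um=3.0, cap_height_um=2.4,
                          center_separation_um=4.2, center_y_um=7.0,
                          rho_basal=5, rho_apical=10, rho_interface=10,
                          activation_rate=0.01)
        geo = AcquisitionGeometry(scan_step=100.0, frames_per_stack=120,
                                  n_stacks=2)
        return scene, geo

    def test_acquisition_plan_frame_count(self):
        scene, geo = self.small()
        acq = simulate_scan_acquisition(scene, geo, geo.n_stacks, seed=0)
        assert acq.movie.shape[0] == geo.frames_per_stack * geo.n_stacks

    def test_every_rendered_event_respects_the_sheet_bound(self):
        scene, geo = self.small()
        acq = simulate_scan_acquisition(scene, geo, geo.n_stacks, seed=1,
                                        render=False)
        assert len(acq.records) > 100
        assert (np.abs(acq.records["z"]) <= geo.sheet_thickness / 2).all()

    def test_emitter_out_of_scan_range_never_rendered(self):
        scene, geo = self.small()
        # scan covers ~12 µm; an emitter needs the sheet within 0.7 µm
        acq = simulate_scan_acquisition(scene, geo, geo.n_stacks, seed=2,
                                        render=False)
        sa, ca = np.sin(geo.angle_rad), np.cos(geo.angle_rad)
        P = acq.truth.positions
        s_star = P[:, 1] - P[:, 2] * ca / sa
        out_of_range = s_star - 700.0 / sa > (geo.frames_per_stack - 1) * geo.scan_step
        rendered = np.unique(acq.records["emitter"])
        assert not np.isin(np.flatnonzero(out_of_range), rendered).any()

    def test_lazy_rendering_matches_materialized_movie(self):
        scene, geo = self.small()
        a = simulate_scan_acquisition(scene, geo, geo.n_stacks, seed=3)
        b = simulate_scan_acquisition(scene, geo, geo.n_stacks, seed=3,
                                      render=False)
        lazy = list(b.iter_frames())
        np.testing.assert_array_equal(a.movie, np.stack(lazy))


class TestTrajectories:
    def test_zero_diffusion_zero_noise_is_static(self):
        true, noisy = simulate_trajectories(5, (0, 0, 0), 0.02, 20, (0, 0, 0), 0)
        assert (np.diff(true, axis=1) == 0).all()
        np.testing.assert_array_equal(true, noisy)

    def test_increment_variance_matches_2_D_dt(self):
        n, F, dt = 100, 80, 0.02
        D = np.array([0.058, 0.059, 0.023])
        true, _ = simulate_trajectories(n, D, dt, F, (0, 0, 0), 11)
        incr = np.diff(true, axis=1)                 # nm
        var = incr.var(axis=(0, 1)) / 1e6            # µm²
        m = n * (F - 1)
        tol = 3 * np.sqrt(2.0 / m)
        np.testing.assert_allclose(var, 2 * D * dt, rtol=tol)

    def test_anisotropic_msd_ordering_preserved(self):
        true, _ = simulate_trajectories(200, (0.06, 0.06, 0.01), 0.02, 40,
                                        (0, 0, 0), 5)
        disp2 = (true[:, -1] - true[:, 0]) ** 2
        mean2 = disp2.mean(axis=0)
        assert mean2[2] < mean2[0] and mean2[2] < mean2[1]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_trajectories(5, (-0.1, 0, 0), 0.02, 10, (0, 0, 0), 0)


class TestFrapSimulation:
    def test_full_recovery_limit(self):
        trace = simulate_frap(tau=10.0, mobile_fraction=1.0, total_time=2000.0,
                              noise=0.0)
        assert abs(trace.normalized[-1] - 1.0) < 1e-6

    def test_immobile_fraction_stays_at_floor(self):
        trace = simulate_frap(tau=15.0, mobile_fraction=0.0, bleach_depth=0.6,
                              noise=0.0)
        post = trace.normalized[trace.bleach_index:]
        np.testing.assert_allclose(post, 0.4, atol=1e-12)

    def test_matches_closed_form_exactly(self):
        tau, mf, depth = 15.0, 0.8, 0.7
        trace = simulate_frap(tau, mf, depth, n_prebleach=3,
                              frame_interval=1.5, total_time=120.0, noise=0.0)
        assert len(trace.t) == 80
        assert trace.bleach_index == 3
        t_post = trace.t[3:]
        expect = recovery_model(t_post, tau, mf, 1 - depth, trace.t[3])
        np.testing.assert_allclose(trace.normalized[3:], expect, atol=1e-12)
        np.testing.assert_allclose(trace.normalized[:3], 1.0, atol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_frap(tau=-1.0, mobile_fraction=0.5)
        with pytest.raises(ValueError):
            simulate_frap(tau=10.0, mobile_fraction=1.5)
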