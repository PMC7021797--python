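"""Astigmatic calibration, spot detection/fitting, z assignment, filtering."""

import numpy as np
import pytest

from llstorm import (
    AcquisitionGeometry,
    AstigCalibration,
    PipelineConfig,
    assign_z,
    calibrate_astigmatism,
    detect_spots,
    filter_localizations,
    fit_spot,
    localization_table,
    localize_movie,
)
from tests.conftest import render_spot


class TestCalibration:
    @staticmethod
    def bead_stack(coef_x, coef_y, z, pixel_size, beads, shape=(96, 96)):
        stack = np.zeros((len(z),) + shape)
        for k, zk in enumerate(z):
            sx = np.polyval(coef_x, zk) / pixel_size
            sy = np.polyval(coef_y, zk) / pixel_size
            for r, c in beads:
                stack[k, r - 10:r + 11, c - 10:c + 11] += render_spot(
                    21, 10.0, 10.0, sx, sy, 50_000.0, 0.0
                )
        return stack + 5.0

    def test_recovers_known_defocus_curves(self, calibration):
        px = 103.8
        z = np.linspace(-700, 700, 15)
        stack = self.bead_stack(calibration.coef_x, calibration.coef_y, z, px,
                                beads=[(30, 30), (30, 70), (70, 48)])
        cal = calibrate_astigmatism(stack, z_step=100.0, pixel_size=px)
        zz = np.linspace(-650, 650, 27)
        assert np.max(np.abs(cal.sigma_x(zz) - calibration.sigma_x(zz))) < 2.0
        assert np.max(np.abs(cal.sigma_y(zz) - calibration.sigma_y(zz))) < 2.0
        assert abs(cal.z0 - calibration.z0) < 10.0

    def test_symmetric_psf_rejected_as_non_astigmatic(self):
        px = 103.8
        z = np.linspace(-700, 700, 15)
        coef = np.polyfit(z, 150 + 100 * (z / 700) ** 2, 4)   # σx ≡ σy
        stack = self.bead_stack(coef, coef, z, px, beads=[(48, 48)])
        with pytest.raises(ValueError, match="astigmatism|monotone"):
            calibrate_astigmatism(stack, z_step=100.0, pixel_size=px)

    def test_too_few_planes_rejected(self, calibration):
        px = 103.8
        z = np.linspace(-200, 200, 3)
        stack = self.bead_stack(calibration.coef_x, calibration.coef_y, z, px,
                                beads=[(48, 48)])
        with pytest.raises(ValueError, match="planes"):
            calibrate_astigmatism(stack, z_step=200.0, pixel_size=px)

    def test_no_beads_rejected(self):
        with pytest.raises(ValueError, match="bead"):
            calibrate_astigmatism(np.ones((11, 64, 64)), 100.0, 103.8)

    def test_save_load_round_trip(self, calibration, tmp_path):
        calibration.save(tmp_path / "cal.yaml")
        back = AstigCalibration.load(tmp_path / "cal.yaml")
        np.testing.assert_allclose(back.coef_x, calibration.coef_x)
        assert back.z_min == calibration.z_min


class TestDetection:
    def test_blank_frame_yields_no_candidates(self):
        assert len(detect_spots(np.full((64, 64), 7.0))) == 0

    def test_isolated_bright_emitters_all_found_at_true_pixels(self):
        frame = np.full((96, 96), 2.0)
        truth = [(i, j) for i in (15, 45, 75) for j in (15, 45, 75)]
        truth.append((30, 60))
        for r, c in truth:
            frame[r - 6:r + 7, c - 6:c + 7] += render_spot(13, 6, 6, 1.4, 1.4,
                                                           2000.0, 0.0)
        found = detect_spots(frame)
        assert len(found) == 10
        assert {tuple(rc) for rc in found} == set(truth)

    def test_adjacent_emitters_merge_to_one_candidate(self):
        frame = np.full((64, 64), 2.0)
        frame[26:39, 26:39] += render_spot(13, 6.0, 6.0, 1.4, 1.4, 2000.0, 0.0)
        frame[26:39, 27:40] += render_spot(13, 6.0, 6.0, 1.4, 1.4, 2000.0, 0.0)
        # brute-force maxima of the rendered image: one peak within min_separation
        assert len(detect_spots(frame, min_separation=4)) == 1


class TestSpotFit:
    def test_noise_free_fit_is_unbiased(self):
        roi = render_spot(13, 6.0, 6.0, 1.5, 1.9, 1500.0, 10.0)
        fit = fit_spot(roi)
        assert fit.converged
        assert abs(fit.x - 6.0) < 0.01 and abs(fit.y - 6.0) < 0.01
        assert abs(fit.photons - 1500.0) < 0.01 * 1500.0

    def test_off_center_spot_recovered(self):
        roi = render_spot(13, 6 + 1.3, 6 - 0.7, 1.5, 1.9, 1500.0, 10.0)
        fit = fit_spot(roi)
        assert abs(fit.x - 7.3) < 0.02 and abs(fit.y - 5.3) < 0.02

    def test_precision_scales_as_inverse_sqrt_photons(self, rng):
        Ns = np.array([250.0, 1000.0, 4000.0])
        sds = []
        for N in Ns:
            expect = render_spot(13, 6.2, 5.9, 1.4, 1.4, N, 0.5)
            xs = [fit_spot(rng.poisson(expect)).x for _ in range(200)]
            sds.append(np.std(xs))
        slope = np.polyfit(np.log(Ns), np.log(sds), 1)[0]
        assert abs(slope - (-0.5)) < 0.1 * 0.5

    def test_degenerate_rois_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_spot(np.zeros((13, 13)))
        with pytest.raises(ValueError):
            fit_spot(np.where(np.eye(13) > 0, np.nan, 1.0))


class TestAssignZ:
    def test_inverts_calibration_over_valid_range(self, calibration):
        for z in np.linspace(-700, 700, 57):
            z_hat, valid = assign_z(calibration.sigma_x(z),
                                    calibration.sigma_y(z), calibration)
            assert valid
            assert abs(z_hat - z) < 1.0

    def test_sampled_width_pair_recovered(self, calibration):
        z_hat, valid = assign_z(calibration.sigma_x(300.0),
                                calibration.sigma_y(300.0), calibration)
        assert valid and abs(z_hat - 300.0) < 5.0

    def test_unachievable_width_pair_flagged_invalid(self, calibration):
        _, valid = assign_z(600.0, 600.0, calibration)   # far off both curves
        assert not valid
        _, valid = assign_z(calibration.sigma_x(5000.0),
                            calibration.sigma_y(5000.0), calibration)
        assert not valid


class TestMovieAndFilter:
    @staticmethod
    def sparse_movie(calibration, rng, n_frames=30):
        geo = AcquisitionGeometry()
        cfg = PipelineConfig(geometry=geo, camera_offset=100.0, camera_gain=1.0)
        px = geo.pixel_size
        truth = []
        frames = np.zeros((n_frames, 64, 64))
        for f in range(n_frames):
            k = rng.integers(2, 5)
            pos = rng.uniform(10, 54, size=(k, 2)) * px
            zs = rng.uniform(-600, 600, size=k)
            for (x, y), z in zip(pos, zs):
                if truth and any(
                    t[0] == f and np.hypot(t[1] - x, t[2] - y) < 12 * px
                    for t in truth
                ):
                    continue
                sx = calibration.sigma_x(z) / px
                sy = calibration.sigma_y(z) / px
                r, c = y / px, x / px
                r0, c0 = int(r) - 8, int(c) - 8
                frames[f, r0:r0 + 17, c0:c0 + 17] += render_spot(
                    17, c - c0, r - r0, sx, sy, 2000.0, 0.0
                )
                truth.append((f, x, y, z))
        movie = 100.0 + rng.poisson(frames + 5.0)
        return movie.astype(np.uint16), truth, cfg

    def test_localizes_sparse_movie_with_high_recall_and_precision(
        self, calibration, rng
    ):
        movie, truth, cfg = self.sparse_movie(calibration, rng)
        table = localize_movie(movie, calibration, cfg)
        d = table.data
        matched = 0
        for f, x, y, z in truth:
            df = d[d["frame"] == f]
            if len(df) and np.hypot(df["x"] - x, df["y"] - y).min() < 250.0:
                matched += 1
        recall = matched / len(truth)
        precision = matched / len(d)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_empty_movie_gives_empty_table(self, calibration):
        cfg = PipelineConfig(camera_offset=100.0)
        movie = np.full((5, 32, 32), 100, np.uint16)
        assert len(localize_movie(movie, calibration, cfg)) == 0

    def test_localization_is_deterministic(self, calibration, rng):
        movie, _, cfg = self.sparse_movie(calibration, rng, n_frames=6)
        t1 = localize_movie(movie, calibration, cfg)
        t2 = localize_movie(movie, calibration, cfg)
        assert t1.data.equals(t2.data)

    def test_filter_keeps_exactly_the_compliant_rows(self, rng):
        n = 1000
        photons = np.full(n, 2000.0)
        z = rng.uniform(-500, 500, n)
        bad = rng.choice(n, size=137, replace=False)
        photons[bad[:70]] = 10.0              # photon violations
        z[bad[70:]] = 900.0                   # axial violations
        table = localization_table(
            np.zeros(n), np.zeros(n), z, np.arange(n), photons=photons
        )
        out, discarded = filter_localizations(table, 500.0, 700.0)
        assert discarded == 137
        assert len(out) == 863
        assert len(out) + discarded == n

    def test_no_op_filter_is_identity(self, rng):
        table = localization_table(
            rng.uniform(0, 1e4, 50), rng.uniform(0, 1e4, 50),
            rng.uniform(-600, 600, 50), np.arange(50),
        )
        out, discarded = filter_localizations(table, 0.0, np.inf)
        assert discarded == 0
        assert out.data.equals(table.data)
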