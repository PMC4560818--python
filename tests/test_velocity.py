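"""Quadratic-surface fitting, gradient inversion, and ROI summaries."""

import numpy as np
import pytest

import cardiomap as cm
from cardiomap.activation import ActivationMap
from cardiomap.velocity import (
    _window_design,
    circular_mean_deg,
    fit_local_surface,
    roi_summaries,
    velocity_from_gradient,
)
from conftest import interior, run_pipeline


def make_map(times, valid=None, pixel_size=1.0, frame_rate=2000.0):
    times = np.asarray(times, float)
    valid = np.ones_like(times, bool) if valid is None else valid
    return ActivationMap(np.where(valid, times, np.nan), valid, frame_rate, pixel_size)


def analytic_times(shape, fn, pixel_size=1.0):
    """Evaluate T = fn(x, y) on the y-up physical grid."""
    X, Y = cm.pixel_coords(shape, pixel_size)
    return fn(X, Y)


class TestFitLocalSurface:
    def test_plane_recovered_exactly(self):
        amap = make_map(analytic_times((5, 5), lambda x, y: 2 + 0.3 * (x - 2) + 0.4 * (y - 2)))
        fit = fit_local_surface(amap, 2, 2, half_width=2)
        assert fit.valid
        assert np.allclose(fit.coefficients, [0, 0, 0, 0.3, 0.4, 2], atol=1e-10)
        assert fit.residual_rms_ms < 1e-10

    def test_pure_quadratic_term(self):
        amap = make_map(analytic_times((5, 5), lambda x, y: (x - 2) ** 2))
        fit = fit_local_surface(amap, 2, 2, half_width=2)
        assert np.allclose(fit.coefficients, [1, 0, 0, 0, 0, 0], atol=1e-10)
        assert fit.gradient == pytest.approx((0.0, 0.0), abs=1e-10)

    def test_matches_independent_normal_equations(self):
        # brute-force oracle: assemble and solve (X'X) b = X'y from scratch
        rng = np.random.default_rng(123)
        for _ in range(50):
            times = rng.normal(10, 3, size=(7, 7))
            valid = rng.random((7, 7)) > 0.3
            valid[3, 3] = True
            if valid.sum() < 8:
                continue
            px = float(rng.uniform(0.5, 3.0))
            amap = make_map(times, valid, pixel_size=px)
            fit = fit_local_surface(amap, 3, 3, half_width=3)
            rows, cols = np.nonzero(valid)
            dx = (cols - 3) * px
            dy = (3 - rows) * px
            X = np.stack([dx**2, dy**2, dx * dy, dx, dy, np.ones_like(dx)], axis=1)
            y = times[rows, cols]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fit.coefficients, beta, atol=1e-8)

    def test_too_few_or_collinear_pixels_invalid(self):
        valid = np.zeros((5, 5), bool)
        valid[2, :] = True  # 5 collinear pixels: rank-deficient design
        amap = make_map(np.arange(25.0).reshape(5, 5), valid)
        assert not fit_local_surface(amap, 2, 2, half_width=2).valid
        valid2 = np.zeros((5, 5), bool)
        valid2[2, 2] = valid2[2, 3] = valid2[3, 2] = True
        amap2 = make_map(np.arange(25.0).reshape(5, 5), valid2)
        assert not fit_local_surface(amap2, 2, 2, half_width=2).valid

    def test_invalid_center_pixel(self):
        valid = np.ones((5, 5), bool)
        valid[2, 2] = False
        amap = make_map(np.zeros((5, 5)), valid)
        assert not fit_local_surface(amap, 2, 2).valid

    def test_center_out_of_bounds_raises(self):
        amap = make_map(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="outside"):
            fit_local_surface(amap, 9, 0)


class TestVelocityFromGradient:
    def test_reciprocal_gradient(self):
        assert velocity_from_gradient(0.1, 0.0) == pytest.approx((10.0, 0.0))

    def test_diagonal_gradient_identity(self):
        vx, vy = velocity_from_gradient(0.1, 0.1)
        assert (vx, vy) == pytest.approx((5.0, 5.0))
        gmag = np.hypot(0.1, 0.1)
        assert np.hypot(vx, vy) * gmag == pytest.approx(1.0, abs=1e-12)

    def test_zero_gradient_invalid(self):
        vx, vy = velocity_from_gradient(0.0, 0.0)
        assert np.isnan(vx) and np.isnan(vy)
        vx, vy = velocity_from_gradient(1e-9, 0.0)  # below the default floor
        assert np.isnan(vx)


class TestVelocityField:
    def test_noiseless_planar_exact(self, planar_run):
        truth, _, _, field = planar_run
        sel = interior(field.validity, 2)
        assert sel.sum() > 500
        assert np.abs(field.vx[sel] - 10.0).max() < 1e-9
        assert np.abs(field.vy[sel]).max() < 1e-9

    def test_radial_vectors_point_outward(self, radial_run):
        truth, _, _, field = radial_run
        rows, cols = np.indices(field.validity.shape)
        r_px = np.hypot(rows - 16, cols - 16)
        sel = field.validity & (r_px > 6)  # radii > 3 x half_width
        ang = field.angle_deg()
        true_ang = np.degrees(np.arctan2(truth.vy, truth.vx)) % 360
        diff = np.abs((ang[sel] - true_ang[sel] + 180) % 360 - 180)
        assert diff.max() < 1.0

    def test_two_region_speeds_recovered_noiseless(self):
        spec = cm.WaveSpec(scenario="two_region", region_speeds=(8.0, 2.0),
                           grid_shape=(24, 48))
        _, _, _, field = run_pipeline(spec)
        cols = np.indices(field.validity.shape)[1]
        b = spec.boundary_col
        left = field.validity & (cols < b - 4)
        right = field.validity & (cols >= b + 4)
        assert abs(field.speed()[left].mean() - 8.0) / 8.0 < 0.02
        assert abs(field.speed()[right].mean() - 2.0) / 2.0 < 0.02

    @pytest.mark.parametrize("phi", [0.0, 30.0, 60.0, 90.0, 150.0, 210.0, 330.0])
    def test_rotation_equivariance(self, phi):
        spec = cm.WaveSpec(scenario="planar", direction_deg=phi, speed_um_per_ms=10.0,
                           grid_shape=(16, 16))
        _, _, _, field = run_pipeline(spec)
        sel = field.validity
        mean_ang = circular_mean_deg(field.angle_deg()[sel])
        err = abs((mean_ang - phi + 180) % 360 - 180)
        assert err < 0.5

    def test_speed_gradient_identity(self, planar_run, radial_run):
        for truth, _, amap, field in (planar_run, radial_run):
            for r, c in zip(*np.nonzero(field.validity)):
                fit = fit_local_surface(amap, r, c)
                gmag = np.hypot(*fit.gradient)
                v = np.hypot(field.vx[r, c], field.vy[r, c])
                assert abs(v * gmag - 1.0) < 1e-12

    def test_residual_filter_excludes_bad_windows(self):
        # corrupt one pixel of a planar map: windows containing it fail the
        # residual bound and are excluded, the rest survive
        spec = cm.WaveSpec(scenario="planar", grid_shape=(16, 16))
        truth, movie = cm.simulate(spec)
        amap = cm.activation_map(cm.normalize_pixels(movie, min_range=0.0))
        amap.times_ms[8, 8] += 50.0
        field = cm.velocity_field(amap)
        assert not field.validity[8, 8]
        assert field.validity[0, 0]

    def test_monotone_degradation_with_noise(self):
        med_errs = []
        for sd in [0.0, 5.0, 10.0, 25.0]:
            spec = cm.WaveSpec(scenario="planar", direction_deg=20.0, grid_shape=(20, 20),
                               speed_um_per_ms=8.0, noise_sd=sd, seed=5)
            _, _, _, field = run_pipeline(spec)
            sel = interior(field.validity, 2)
            med_errs.append(np.median(np.abs(field.speed()[sel] - 8.0)))
        assert all(a <= b + 1e-12 for a, b in zip(med_errs, med_errs[1:]))


class TestROISummaries:
    def _uniform_field(self, vx, vy, shape=(8, 8)):
        return cm.VelocityField(np.full(shape, float(vx)), np.full(shape, float(vy)),
                                np.ones(shape, bool), 1.0)

    def test_uniform_vectors(self):
        rois = roi_summaries(self._uniform_field(3.0, 4.0), roi_size=8)
        assert len(rois) == 1
        assert rois[0].mean_speed == pytest.approx(5.0)
        assert rois[0].mean_angle_deg == pytest.approx(np.degrees(np.arctan2(4, 3)), abs=1e-9)

    def test_circular_mean_of_orthogonal_vectors(self):
        field = self._uniform_field(1.0, 0.0, shape=(2, 2))
        field.vx[0] = 1.0
        field.vy[0] = 0.0
        field.vx[1] = 0.0
        field.vy[1] = 1.0
        rois = roi_summaries(field, roi_size=2)
        assert rois[0].mean_angle_deg == pytest.approx(45.0)
        assert rois[0].mean_speed == pytest.approx(1.0)

    def test_empty_roi_reported_without_statistics(self):
        field = self._uniform_field(1.0, 0.0, shape=(8, 8))
        field.validity[:, 4:] = False
        field.validity[0, 7] = True  # stretch the bounding box across two tiles
        field.vx[0, 7], field.vy[0, 7] = 1.0, 0.0
        field.validity[1:, 4:] = False
        rois = roi_summaries(field, roi_size=4)
        assert any(r.n_vectors == 0 and np.isnan(r.mean_speed) for r in rois)

    def test_matches_brute_force_aggregation(self, planar_run):
        _, _, _, field = planar_run
        rois = roi_summaries(field, roi_size=8)
        speed = field.speed()
        for roi in rois:
            sel = field.validity[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]
            vals = speed[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop][sel]
            assert roi.n_vectors == sel.sum()
            if roi.n_vectors:
                assert roi.mean_speed == pytest.approx(float(np.mean(vals)))

    def test_roi_size_validated(self, planar_run):
        _, _, _, field = planar_run
        with pytest.raises(ValueError):
            roi_summaries(field, roi_size=1)
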