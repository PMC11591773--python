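"""Triangulation model, stripe localisation, renderer, calibration, distortion."""

import numpy as np
import pytest

from lastfit import laser, synthetic
from lastfit.exceptions import (
    CalibrationDesignError,
    FieldOfViewError,
    NoLineError,
    NoPeakError,
)
from lastfit.ga import GAConfig
from lastfit.laser import (
    CameraGeometry,
    build_calibration_search_space,
    build_distortion_table,
    calibration_objective,
    default_geometry,
    detect_line_edges,
    height_to_pixel,
    reconstruct_surface,
    render_scan,
    stripe_peak_subpixel,
    stripe_peaks_rows,
    triangulate_height,
    triangulate_width,
    width_to_pixel,
)


class TestTriangulation:
    def test_glass_plane_reference(self):
        geom = default_geometry()
        # displacement that maps exactly to the z = 0 reference plane
        x = geom.x_center + geom.a1 * geom.d / (geom.a2 * geom.pixel_size)
        assert triangulate_height(x, geom) == pytest.approx(0.0, abs=1e-9)

    def test_forward_inverse_round_trip(self, rng):
        for _ in range(1000):
            geom = CameraGeometry(
                x_center=rng.uniform(50, 300),
                y_center=rng.uniform(50, 300),
                pixel_size=rng.uniform(0.01, 0.1),
                a1=rng.uniform(15, 30),
                a2=rng.uniform(30, 120),
                d=rng.uniform(50, 200),
            )
            z = rng.uniform(0, 40)
            assert triangulate_height(height_to_pixel(z, geom), geom) == pytest.approx(
                z, abs=1e-9
            )

    def test_height_decreasing_in_column(self):
        geom = default_geometry()
        xs = np.linspace(geom.x_center + 50, geom.x_center + 500, 64)
        zs = triangulate_height(xs, geom)
        assert np.all(np.diff(zs) < 0)

    def test_singular_displacement(self):
        geom = default_geometry()
        with pytest.raises(FieldOfViewError):
            triangulate_height(geom.x_center, geom)

    def test_width_on_axis_row(self):
        geom = default_geometry()
        assert triangulate_width(geom.y_center, 5.0, geom) == pytest.approx(
            geom.pixel_size * geom.y_center
        )

    def test_width_round_trip(self, rng):
        geom = default_geometry()
        for _ in range(200):
            y, z = rng.uniform(5, 100), rng.uniform(0, 40)
            yb = width_to_pixel(y, z, geom)
            assert triangulate_width(yb, z, geom) == pytest.approx(y, abs=1e-9)

    def test_width_affine_in_row(self):
        geom = default_geometry()
        rows = np.array([100.0, 200.0, 300.0])
        ys = triangulate_width(rows, 10.0, geom)
        assert np.diff(ys)[0] == pytest.approx(np.diff(ys)[1])


class TestStripePeak:
    def test_symmetric_triangle_centre(self):
        x = np.arange(25.0)
        profile = np.maximum(0.0, 10.0 - np.abs(x - 12.0))
        # symmetry pins the centre; residual is the u-bisection tolerance
        assert stripe_peak_subpixel(profile) == pytest.approx(12.0, abs=1e-4)

    def test_gaussian_subpixel_centre(self):
        x = np.arange(21.0)
        profile = np.exp(-0.5 * ((x - 10.30) / 2.0) ** 2)
        assert stripe_peak_subpixel(profile) == pytest.approx(10.30, abs=0.05)

    def test_bias_below_threshold_across_phases(self):
        # noise-free Gaussian stripes, sub-pixel phases 0.0 .. 0.9
        x = np.arange(64.0)
        for phase in np.arange(0.0, 1.0, 0.1):
            c = 30.0 + phase
            profile = 217 * np.exp(-0.5 * ((x - c) / 2.0) ** 2)
            assert stripe_peak_subpixel(profile) == pytest.approx(c, abs=0.02)

    def test_bisection_matches_grid_search(self):
        from lastfit.laser import _bezier_curve_derivative, _peak_windows

        x = np.arange(40.0)
        profile = 200 * np.exp(-0.5 * ((x - 17.6) / 2.5) ** 2)
        centers, half = _peak_windows(profile[None, :], 7, 0.2)
        H = int(half[0])
        idx = np.arange(centers[0] - H, centers[0] + H + 1)
        I_ctrl = profile[idx][None, :]
        us = np.linspace(0.05, 0.95, 10_001)
        d = _bezier_curve_derivative(np.repeat(I_ctrl, us.size, axis=0), us)
        k = np.flatnonzero(np.sign(d[:-1]) != np.sign(d[1:]))[0]
        # linear interpolation of the sign change refines the grid root
        u_grid = us[k] + (us[k + 1] - us[k]) * d[k] / (d[k] - d[k + 1])
        x_ctrl = idx.astype(float)[None, :]
        est = stripe_peak_subpixel(profile)
        from lastfit.laser import _bezier_curve_value

        x_grid = _bezier_curve_value(x_ctrl, np.array([u_grid]))[0]
        assert est == pytest.approx(x_grid, abs=1e-4)

    def test_flat_row_raises(self):
        with pytest.raises(NoPeakError):
            stripe_peak_subpixel(np.full(32, 5.0))


class TestLineEdges:
    def test_ideal_step_profile(self):
        p = np.zeros(200)
        p[40:161] = 1.0
        start, end = detect_line_edges(p, smooth=1)
        assert (start, end) == (40, 160)

    def test_uniform_profile_raises(self):
        with pytest.raises(NoLineError):
            detect_line_edges(np.ones(100))

    def test_rendered_edges_near_truth(self, footprint):
        geom = default_geometry()
        stack = render_scan(footprint, geom, seed=0)
        img = stack.images[0].astype(float)
        start, end = detect_line_edges(img.max(axis=1))
        z_col = footprint.heights[0]
        yb = width_to_pixel(footprint.y_coords, z_col, geom)
        assert start == pytest.approx(min(yb[0], yb[-1]), abs=3)
        assert end == pytest.approx(max(yb[0], yb[-1]), abs=3)


class TestRenderer:
    def test_flat_surface_straight_stripe(self):
        from lastfit.grid import SurfaceGrid

        geom = default_geometry()
        x = np.linspace(50, 150, 6)
        y = np.linspace(20, 80, 6)
        flat = SurfaceGrid(np.full((6, 6), 20.0), x, y)
        stack = render_scan(flat, geom, seed=0)
        expected = height_to_pixel(20.0, geom)
        for img in stack.images:
            peaks = stripe_peaks_rows(img[img.max(axis=1) > 100].astype(float))
            np.testing.assert_allclose(peaks, expected, atol=0.05)

    def test_reproducible_from_seed(self, footprint):
        geom = default_geometry()
        s1 = render_scan(footprint, geom, noise_level=0.01, seed=42)
        s2 = render_scan(footprint, geom, noise_level=0.01, seed=42)
        np.testing.assert_array_equal(s1.images, s2.images)

    def test_peak_recovery_on_noise_free_render(self, footprint):
        geom = default_geometry()
        stack = render_scan(footprint, geom, seed=0)
        i = 10
        img = stack.images[i].astype(float)
        start, end = detect_line_edges(img.max(axis=1))
        rows = np.arange(start + 2, end - 2)
        peaks = stripe_peaks_rows(img[start + 2 : end - 2])
        z_col = footprint.heights[i]
        yb = width_to_pixel(footprint.y_coords, z_col, geom)
        xb = height_to_pixel(z_col, geom)
        order = np.argsort(yb)
        truth = np.interp(rows, yb[order], xb[order])
        ok = np.isfinite(peaks)
        # 8-bit quantisation adds a little beyond the pure detector bias
        assert np.nanmax(np.abs(peaks[ok] - truth[ok])) < 0.05

    def test_off_sensor_raises(self, footprint):
        geom = CameraGeometry(
            x_center=630.0, y_center=60.0, pixel_size=0.06, a1=20.0, a2=64.0, d=110.0
        )
        with pytest.raises(FieldOfViewError):
            render_scan(footprint, geom, seed=0)


class TestReconstruction:
    def test_round_trip_rms(self, footprint):
        geom = default_geometry()
        stack = render_scan(footprint, geom, seed=1)
        recon = reconstruct_surface(
            stack.images, stack.slider_positions, geom, y_grid=footprint.y_coords
        )
        rms = np.sqrt(np.mean((recon.heights - footprint.heights) ** 2))
        assert rms < 0.05

    def test_flat_target_plane(self):
        from lastfit.grid import SurfaceGrid

        geom = default_geometry()
        x = np.linspace(50, 150, 8)
        y = np.linspace(20, 80, 31)
        flat = SurfaceGrid(np.full((8, 31), 15.0), x, y)
        stack = render_scan(flat, geom, seed=0)
        recon = reconstruct_surface(stack.images, stack.slider_positions, geom, y_grid=y)
        assert np.max(np.abs(recon.heights - 15.0)) < 0.01

    def test_noise_degrades_gracefully(self, footprint):
        geom = default_geometry()
        stack = render_scan(footprint, geom, noise_level=0.01, seed=3)
        recon = reconstruct_surface(
            stack.images, stack.slider_positions, geom, y_grid=footprint.y_coords
        )
        rms = np.sqrt(np.mean((recon.heights - footprint.heights) ** 2))
        assert rms < 0.2


class TestCalibrationObjective:
    def test_zero_at_generating_parameters(self):
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, seed=0)
        assert calibration_objective(geom, data) == pytest.approx(0.0, abs=1e-20)

    def test_positive_under_perturbation(self):
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, seed=0)
        for field in ("x_center", "y_center", "pixel_size", "a1", "a2", "d"):
            kw = {f: getattr(geom, f) for f in ("x_center", "y_center", "pixel_size", "a1", "a2", "d")}
            kw[field] = kw[field] * 1.05
            assert calibration_objective(CameraGeometry(**kw), data) > 1e-8

    def test_identifiability_slices(self):
        # FO has a strict minimum at the truth along every 1-D parameter slice
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, seed=0)
        fields = ("x_center", "y_center", "pixel_size", "a1", "a2", "d")
        base = {f: getattr(geom, f) for f in fields}
        for field in fields:
            for factor in (0.98, 1.02):
                kw = dict(base)
                kw[field] = kw[field] * factor
                assert calibration_objective(CameraGeometry(**kw), data) > 1e-10

    def test_matches_two_loop_sums(self, rng):
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, noise_px=0.5, seed=1)
        cand = CameraGeometry(
            geom.x_center - 5, geom.y_center + 3, geom.pixel_size, geom.a1 * 1.02,
            geom.a2 * 0.98, geom.d * 1.01,
        )
        k = cand.a1 * cand.d
        r1 = []
        for dz, xp, xr in zip(data.dz, data.x_pix, data.x_ref_pix):
            pred = k / (cand.pixel_size * (xp - cand.x_center)) - k / (
                cand.pixel_size * (xr - cand.x_center)
            )
            r1.append((dz - pred) ** 2)
        r2 = []
        for dy, yp, yr, zy, zr in zip(
            data.dy, data.y_pix, data.y_ref_pix, data.z_at_y, data.z_at_y_ref
        ):
            pred = (
                cand.pixel_size * (yp - cand.y_center) * (cand.a2 + zy) / cand.a1
                - cand.pixel_size * (yr - cand.y_center) * (cand.a2 + zr) / cand.a1
            )
            r2.append((dy - pred) ** 2)
        brute = 0.5 * (np.mean(r1) + np.mean(r2))
        assert calibration_objective(cand, data) == pytest.approx(brute, rel=1e-12)


class TestCalibrationSearchSpace:
    def test_printed_multipliers_for_8mm_lens(self):
        space = build_calibration_search_space((480, 640), 8.0)
        # gene order: xc, yc, eta, a1, a2, d
        assert space.lower[3] == pytest.approx(14.4)
        assert space.upper[3] == pytest.approx(30.4)
        assert space.lower[4] == pytest.approx(30.4)
        assert space.upper[4] == pytest.approx(304.0)
        assert space.lower[5] == pytest.approx(30.4)
        assert space.upper[5] == pytest.approx(243.2)

    def test_principal_point_bounded_by_sensor(self):
        space = build_calibration_search_space((480, 640), 8.0)
        assert (space.lower[0], space.upper[0]) == (0.0, 640.0)
        assert (space.lower[1], space.upper[1]) == (0.0, 480.0)


class TestCalibrate:
    def test_objective_reduced_below_random_sampling(self):
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, seed=0)
        result = laser.calibrate(
            data, (480, 640), 8.0,
            GAConfig(seed=0, max_generations=200, stall_window=50, stall_tolerance=1e-18),
            pixel_pitch=geom.pixel_size, n_stages=60,
        )
        space = build_calibration_search_space((480, 640), 8.0, pixel_pitch=geom.pixel_size)
        rng = np.random.default_rng(1)
        samples = space.sample(rng, 10_000)
        fo = np.array(
            [calibration_objective(CameraGeometry.from_vector(s), data) for s in samples]
        )
        assert result.objective <= np.nanmin(fo[np.isfinite(fo)])

    def test_underdetermined_data_rejected(self):
        geom = default_geometry()
        data = synthetic.make_calibration_target(geom, n_steps=2, n_rows=2, seed=0)
        assert data.underdetermined
        with pytest.raises(CalibrationDesignError):
            laser.calibrate(data, (480, 640), 8.0)


class TestDistortion:
    def test_clean_traces_give_zero_tables(self):
        x0, step = 320.0, 12.0
        traces = x0 - np.arange(8)[:, None] * step + np.zeros((8, 30))
        table = build_distortion_table(traces, np.arange(8) * 2.0)
        np.testing.assert_allclose(table.delta_x, 0.0, atol=1e-10)
        np.testing.assert_allclose(table.delta_y, 0.0, atol=1e-10)

    def test_reference_line_anchored_at_zero(self, rng):
        traces = 320.0 - np.arange(8)[:, None] * 12.0 + rng.normal(0, 0.2, (8, 30))
        table = build_distortion_table(traces, np.arange(8) * 2.0)
        assert table.delta_x[0] == 0.0

    def test_injected_shift_recovered(self):
        # barrel-like per-line distortion on otherwise ideal equal steps
        delta = np.array([0.0, 0.0, -0.3, -0.8, -1.4, -2.1])
        ideal = 320.0 - np.arange(6)[:, None] * 15.0 + np.zeros((6, 20))
        observed = ideal - delta[:, None]
        table = build_distortion_table(observed, np.arange(6) * 2.0)
        # delta_x is identified up to the linear trend absorbed by the
        # first-step shift estimate (here the first step is distortion-free)
        np.testing.assert_allclose(table.delta_x, delta, atol=1e-9)

    def test_unequal_steps_rejected(self):
        traces = np.zeros((5, 10))
        with pytest.raises(CalibrationDesignError):
            build_distortion_table(traces, np.array([0.0, 2.0, 4.1, 6.0, 8.4]))

    def test_corrected_reconstruction_beats_uncorrected(self, footprint):
        from lastfit.laser import DistortionTable

        geom = default_geometry()
        nx = footprint.shape[0]
        idx = np.arange(nx)
        barrel = -0.8 * ((idx - nx / 2) / (nx / 2)) ** 2
        table = DistortionTable(delta_x=barrel, delta_y=np.zeros(480))
        stack = render_scan(footprint, geom, seed=2, distortion=table)
        kwargs = dict(y_grid=footprint.y_coords)
        rec_raw = reconstruct_surface(stack.images, stack.slider_positions, geom, **kwargs)
        rec_cor = reconstruct_surface(
            stack.images, stack.slider_positions, geom, distortion=table, **kwargs
        )
        rms_raw = np.sqrt(np.mean((rec_raw.heights - footprint.heights) ** 2))
        rms_cor = np.sqrt(np.mean((rec_cor.heights - footprint.heights) ** 2))
        assert rms_cor < rms_raw
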