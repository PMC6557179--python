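import math

import numpy as np
import pytest

from sxpre.calib import (InsufficientRingsError, NoIntersectionError,
                         PowderPeakSet, calibrate, calibrate_step1,
                         cluster_rings, estimate_beam_center, fit_center_line,
                         fit_polar_tilt, project_ring, refine_geometry,
                         residual, two_theta_of_pixel)
from sxpre.core import CalibrantSpec, Geometry, two_theta_from_d
from sxpre.synth import default_ring_spec, generate_powder_peaks

PSI = np.linspace(0, 2 * math.pi, 60, endpoint=False)


def _peaks_from_rings(geometry, two_thetas, psi=PSI):
    xs, ys = [], []
    for tth in two_thetas:
        x, y = project_ring(geometry, tth, psi)
        xs.append(np.atleast_1d(x))
        ys.append(np.atleast_1d(y))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return PowderPeakSet(x, y, np.ones(len(x)))


class TestForwardModel:
    def test_untilted_rings_are_circles(self, untilted_geometry):
        tth = math.atan(0.1)  # tan(2theta) = 0.1 -> 100 px radius at D=100mm
        x, y = project_ring(untilted_geometry, tth, PSI)
        radii = np.hypot(x - 720.0, y - 720.0)
        np.testing.assert_allclose(radii, 100.0, rtol=1e-12)

    def test_untilted_antipodal_symmetry(self, untilted_geometry):
        for psi in (0.3, 1.2, 2.5):
            x1, y1 = project_ring(untilted_geometry, 0.4, psi)
            x2, y2 = project_ring(untilted_geometry, 0.4, psi + math.pi)
            r1 = math.hypot(x1 - 720, y1 - 720)
            r2 = math.hypot(x2 - 720, y2 - 720)
            assert r1 == pytest.approx(r2, rel=1e-12)

    def test_forward_inverse_consistency(self, tilted_geometry,
                                         untilted_geometry):
        for geom in (untilted_geometry, tilted_geometry):
            for tth in (0.05, 0.2, 0.45, 0.7):
                x, y = project_ring(geom, tth, PSI)
                back = two_theta_of_pixel(geom, x, y)
                np.testing.assert_allclose(back, tth, atol=1e-9)

    def test_grazing_ray_rejected(self):
        geom = Geometry(beam_center=(0, 0), distance_mm=100.0,
                        pixel_size_mm=0.1, photon_energy_ev=12000.0,
                        tilt_polar=0.05, tilt_azimuth=0.0)
        with pytest.raises(NoIntersectionError):
            project_ring(geom, 1.55, math.pi)  # 2theta + tilt > pi/2

    @pytest.mark.parametrize("theta_t", [0.005, 0.01, 0.02, 0.05])
    def test_small_tilt_center_offset_law(self, theta_t):
        # ellipse-centre offset (midpoint of the two extremes along the
        # tilt direction) matches D*tan(theta_t)*tan^2(2theta) within 1%
        phi_t = math.radians(30.0)
        geom = Geometry(beam_center=(720.0, 720.0), distance_mm=100.0,
                        pixel_size_mm=0.1, photon_energy_ev=12000.0,
                        tilt_polar=theta_t, tilt_azimuth=phi_t)
        for tth in (0.2, 0.35, 0.5):
            p1 = np.array(project_ring(geom, tth, phi_t))
            p2 = np.array(project_ring(geom, tth, phi_t + math.pi))
            offset = np.linalg.norm((p1 + p2) / 2 - np.array([720.0, 720.0]))
            predicted = (100.0 * math.tan(theta_t) * math.tan(tth) ** 2 / 0.1)
            assert offset == pytest.approx(predicted, rel=0.01)


class TestClustering:
    def test_well_separated_radii(self, untilted_geometry):
        angles = 2 * math.pi * np.arange(5) / 5
        radii = np.array([100.1, 99.9, 100.0, 200.2, 199.8])
        x = 720 + radii * np.cos(angles)
        y = 720 + radii * np.sin(angles)
        peaks = PowderPeakSet(x, y, np.ones(5))
        clusters = cluster_rings(peaks, untilted_geometry, eps=1.0,
                                 min_samples=2)
        assert [c.n_peaks for c in clusters] == [3, 2]
        assert clusters[0].mean_radius < clusters[1].mean_radius

    def test_outlier_marked_noise(self, untilted_geometry):
        radii = np.array([100.0, 100.1, 99.9, 500.0])
        x = 720 + radii
        y = np.full(4, 720.0)
        peaks = PowderPeakSet(x, y, np.ones(4))
        clusters = cluster_rings(peaks, untilted_geometry, eps=1.0,
                                 min_samples=2)
        assert len(clusters) == 1
        assert clusters[0].n_peaks == 3

    def test_untilted_cluster_centers_at_beam_center(self, untilted_geometry):
        peaks = _peaks_from_rings(untilted_geometry, [0.2, 0.4])
        clusters = cluster_rings(peaks, untilted_geometry)
        for c in clusters:
            assert c.center[0] == pytest.approx(720.0, abs=1e-9)
            assert c.center[1] == pytest.approx(720.0, abs=1e-9)

    def test_scattering_angle_from_radius(self, untilted_geometry):
        peaks = _peaks_from_rings(untilted_geometry, [0.3])
        (cluster,) = cluster_rings(peaks, untilted_geometry)
        assert cluster.two_theta == pytest.approx(0.3, rel=1e-9)


class TestStepOneFits:
    def test_untilted_reports_tilt_undetectable(self, untilted_geometry):
        peaks = _peaks_from_rings(untilted_geometry, [0.2, 0.35, 0.5])
        clusters = cluster_rings(peaks, untilted_geometry)
        _line, phi_t, detected = fit_center_line(clusters)
        assert not detected
        assert phi_t == 0.0

    def test_azimuth_recovered_within_half_degree(self, tilted_geometry):
        peaks = _peaks_from_rings(tilted_geometry, [0.2, 0.35, 0.5])
        clusters = cluster_rings(peaks, tilted_geometry)
        _line, phi_t, detected = fit_center_line(clusters)
        assert detected
        assert math.degrees(abs(phi_t - tilted_geometry.tilt_azimuth)) < 0.5

    def test_two_cluster_line_interpolates_centers(self, tilted_geometry):
        peaks = _peaks_from_rings(tilted_geometry, [0.25, 0.5])
        clusters = cluster_rings(peaks, tilted_geometry)
        line, _phi, detected = fit_center_line(clusters)
        assert detected
        for c in clusters:
            assert c.center[1] == pytest.approx(
                line.slope * c.center[0] + line.intercept, abs=1e-9)

    def test_single_cluster_rejected(self, untilted_geometry):
        peaks = _peaks_from_rings(untilted_geometry, [0.3])
        clusters = cluster_rings(peaks, untilted_geometry)
        with pytest.raises(InsufficientRingsError):
            fit_center_line(clusters)

    def test_polar_tilt_recovered_within_two_percent(self, tilted_geometry):
        peaks = _peaks_from_rings(tilted_geometry, [0.2, 0.3, 0.4, 0.5, 0.6])
        clusters = cluster_rings(peaks, tilted_geometry)
        line, _phi, _ = fit_center_line(clusters)
        theta = fit_polar_tilt(clusters, tilted_geometry, line)
        assert theta == pytest.approx(0.02, rel=0.02)

    def test_polar_tilt_scales_with_distance(self, tilted_geometry):
        # at fixed theta_t, the centre-offset slope against tan^2(2theta)
        # is proportional to D; each dataset fitted with its own distance
        # recovers the same tilt
        far = tilted_geometry.replace(distance_mm=200.0)
        angles = [0.2, 0.3, 0.4, 0.5]
        slopes = {}
        for geom in (tilted_geometry, far):
            peaks = _peaks_from_rings(geom, angles)
            clusters = cluster_rings(peaks, geom)
            line, _phi, _ = fit_center_line(clusters)
            theta = fit_polar_tilt(clusters, geom, line)
            assert theta == pytest.approx(0.02, rel=0.02)
            u = np.asarray(line.direction)
            o1 = np.asarray(clusters[0].center)
            delta = np.array([(np.asarray(c.center) - o1) @ u
                              for c in clusters])
            greg = np.array([math.tan(c.two_theta) ** 2 for c in clusters])
            slopes[geom.distance_mm] = np.polyfit(greg - greg[0], delta, 1)[0]
        assert slopes[200.0] == pytest.approx(2 * slopes[100.0], rel=0.02)

    def test_beam_center_untilted(self, untilted_geometry):
        peaks = _peaks_from_rings(untilted_geometry, [0.2, 0.4])
        clusters = cluster_rings(peaks, untilted_geometry)
        line, _phi, detected = fit_center_line(clusters)
        bc = estimate_beam_center(clusters, line, 0.0, detected,
                                  untilted_geometry)
        assert bc[0] == pytest.approx(720.0, abs=1e-6)
        assert bc[1] == pytest.approx(720.0, abs=1e-6)

    def test_beam_center_tilted_within_half_pixel(self, tilted_geometry):
        peaks = _peaks_from_rings(tilted_geometry, [0.2, 0.3, 0.4, 0.5])
        geom1, _ = calibrate_step1(peaks, tilted_geometry)
        err = math.hypot(geom1.beam_center[0] - 726.0,
                         geom1.beam_center[1] - 715.0)
        assert err < 0.5

    def test_beam_center_translation_equivariance(self, tilted_geometry):
        peaks = _peaks_from_rings(tilted_geometry, [0.2, 0.3, 0.4, 0.5])
        dx, dy = 5.0, -3.0
        shifted = PowderPeakSet(peaks.x + dx, peaks.y + dy, peaks.intensity)
        shifted_initial = tilted_geometry.replace(
            beam_center=(726.0 + dx, 715.0 + dy))
        g1, _ = calibrate_step1(peaks, tilted_geometry)
        g2, _ = calibrate_step1(shifted, shifted_initial)
        assert g2.beam_center[0] - g1.beam_center[0] == pytest.approx(dx,
                                                                      abs=1e-6)
        assert g2.beam_center[1] - g1.beam_center[1] == pytest.approx(dy,
                                                                      abs=1e-6)


class TestResidual:
    def test_zero_under_generating_geometry(self, tilted_geometry):
        angles = [0.2, 0.35, 0.5]
        peaks = _peaks_from_rings(tilted_geometry, angles)
        clusters = cluster_rings(peaks, tilted_geometry)
        assert residual(tilted_geometry, clusters, angles) == pytest.approx(
            0.0, abs=1e-18)

    def test_invariant_under_relabelling(self, tilted_geometry, rng):
        angles = [0.2, 0.35, 0.5]
        peaks = _peaks_from_rings(tilted_geometry, angles)
        clusters = cluster_rings(peaks, tilted_geometry)
        r1 = residual(tilted_geometry, clusters, angles)
        for c in clusters:
            c.positions = c.positions[rng.permutation(len(c.positions))]
        assert residual(tilted_geometry, clusters, angles) == pytest.approx(
            r1, rel=1e-12, abs=1e-18)

    def test_distance_perturbation_increases_residual(self, tilted_geometry):
        angles = [0.2, 0.35, 0.5]
        peaks = _peaks_from_rings(tilted_geometry, angles)
        clusters = cluster_rings(peaks, tilted_geometry)
        perturbed = tilted_geometry.replace(distance_mm=101.0)
        assert residual(perturbed, clusters, angles) > residual(
            tilted_geometry, clusters, angles)


class TestRefinement:
    def test_noiseless_parameter_recovery(self):
        spec = default_ring_spec(seed=3)
        peaks, truth = generate_powder_peaks(spec)
        true = truth["geometry"]
        initial = Geometry(beam_center=(720.0, 720.0), distance_mm=102.0,
                           pixel_size_mm=0.1, photon_energy_ev=12000.0)
        result = calibrate(peaks, initial, spec.calibrant)
        g = result.geometry
        assert math.hypot(g.beam_center[0] - true.beam_center[0],
                          g.beam_center[1] - true.beam_center[1]) < 0.05
        assert abs(g.distance_mm - true.distance_mm) < 0.001 * true.distance_mm
        assert abs(g.tilt_polar - true.tilt_polar) < 0.01 * true.tilt_polar
        assert math.degrees(abs(g.tilt_azimuth - true.tilt_azimuth)) < 0.5
        assert result.residual_R <= result.step1_residual

    def test_noisy_recovery_within_tolerance(self):
        spec = default_ring_spec(seed=3, position_noise_sigma=0.2)
        peaks, truth = generate_powder_peaks(spec)
        true = truth["geometry"]
        initial = Geometry(beam_center=(720.0, 720.0), distance_mm=102.0,
                           pixel_size_mm=0.1, photon_energy_ev=12000.0)
        g = calibrate(peaks, initial, spec.calibrant).geometry
        assert math.hypot(g.beam_center[0] - true.beam_center[0],
                          g.beam_center[1] - true.beam_center[1]) < 0.5
        assert abs(g.distance_mm - true.distance_mm) < 0.005 * true.distance_mm

    def test_fixed_point_at_true_optimum(self):
        spec = default_ring_spec(seed=3)
        peaks, truth = generate_powder_peaks(spec)
        true = truth["geometry"]
        clusters = cluster_rings(peaks, true)
        result = refine_geometry(true, clusters, spec.calibrant)
        g = result.geometry
        assert math.hypot(g.beam_center[0] - true.beam_center[0],
                          g.beam_center[1] - true.beam_center[1]) < 1e-6
        assert g.distance_mm == pytest.approx(true.distance_mm, rel=1e-8)

    def test_ring_count_mismatch_rejected(self):
        spec = default_ring_spec(seed=3)
        peaks, truth = generate_powder_peaks(spec)
        clusters = cluster_rings(peaks, truth["geometry"])
        short = CalibrantSpec("short", spec.calibrant.d_spacings[:3])
        with pytest.raises(ValueError, match="3 d spacings"):
            refine_geometry(truth["geometry"], clusters, short)

    def test_model_angles_follow_bragg_law(self):
        spec = default_ring_spec(seed=3)
        wavelength = spec.geometry.wavelength
        angles = [two_theta_from_d(wavelength, d)
                  for d in spec.calibrant.d_spacings]
        assert all(a < b for a, b in zip(angles, angles[1:]))
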