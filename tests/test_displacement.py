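"""Flow displacement, rotational angle gating, and rotational speed."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortaflow import displacement as disp
from aortaflow import flow as afflow
from aortaflow.io import equivalent_diameter_mm
from aortaflow.synth import JetParams, rotating_offset_trajectory, simulate_velocity_series
from conftest import disc_mask


def brute_force_fd(vel, mask, spacing, sign):
    """Independent per-pixel recomputation of FD (loop, no vectorisation)."""
    sr, sc = spacing
    xs, ys, n = 0.0, 0.0, 0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                xs += x
                ys += y
                n += 1
    vcx, vcy = xs / n, ys / n
    wx = wy = wtot = 0.0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                w = max(sign * vel[y, x], 0.0)
                wx += w * x
                wy += w * y
                wtot += w
    if wtot == 0:
        return math.nan
    dx = (wx / wtot - vcx) * sc
    dy = (wy / wtot - vcy) * sr
    d_eq = 2 * math.sqrt(n * sr * sc / math.pi)
    return 100.0 * math.hypot(dx, dy) / d_eq


class TestCentroids:
    def test_centered_disc(self):
        m = disc_mask(65, 20.0)
        assert disp.vessel_center(m) == pytest.approx((32.0, 32.0))

    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[7, 5] = True  # row 7, col 5 -> (x=5, y=7)
        assert disp.vessel_center(m) == (5.0, 7.0)

    def test_random_mask_matches_bruteforce(self, rng):
        m = rng.random((24, 24)) > 0.6
        m[12, 12] = True
        cx, cy = disp.vessel_center(m)
        ys, xs = np.nonzero(m)
        assert cx == pytest.approx(xs.mean(), abs=1e-12)
        assert cy == pytest.approx(ys.mean(), abs=1e-12)

    def test_uniform_velocity_cov_equals_center(self):
        m = disc_mask(33, 10.0)
        vel = np.where(m, 5.0, 0.0)
        assert disp.center_of_velocity(vel, m, +1) == pytest.approx(disp.vessel_center(m))

    def test_all_flow_in_one_pixel(self):
        m = disc_mask(33, 10.0)
        vel = np.zeros((33, 33))
        vel[20, 18] = 30.0
        assert disp.center_of_velocity(vel, m, +1) == (18.0, 20.0)

    def test_gaussian_jet_center_recovered(self):
        # narrow jet well inside the lumen: truncation bias < 0.1 px
        p = JetParams(offset_fraction=0.10, offset_angle_deg=37.0, jet_sigma_fraction=0.15)
        series, masks, gt = simulate_velocity_series(p)
        i = 5  # near peak systole
        cov = disp.center_of_velocity(series.frames[i].velocity, masks.frames[i], +1)
        vc = disp.vessel_center(masks.frames[i])
        d_eq = equivalent_diameter_mm(masks.frames[i].sum() * 0.25)
        ux, uy = disp.angle_to_unit(gt.angle_deg[i])
        off_px = gt.fd_pct[i] / 100.0 * d_eq / 0.5  # spacing 0.5 mm
        expected = (vc[0] + off_px * ux, vc[1] + off_px * uy)
        assert cov == pytest.approx(expected, abs=0.1)

    def test_no_forward_pixels_returns_none(self):
        m = disc_mask(17, 5.0)
        vel = np.where(m, -3.0, 0.0)
        assert disp.center_of_velocity(vel, m, +1) is None


class TestFlowDisplacementFrame:
    def test_axisymmetric_profile_is_zero(self):
        grid = 65
        m = disc_mask(grid, 20.0)
        yy, xx = np.mgrid[0:grid, 0:grid]
        rho2 = (yy - 32.0) ** 2 + (xx - 32.0) ** 2
        vel = np.where(m, 50.0 * np.maximum(1 - rho2 / 400.0, 0), 0.0)
        fd, _ = disp.flow_displacement_frame(vel, m, (1.0, 1.0), +1)
        assert fd <= 1e-9

    def test_point_jet_at_quarter_diameter(self):
        grid = 101
        m = disc_mask(grid, 40.0)
        d_eq = equivalent_diameter_mm(m.sum() * 1.0)
        vc = disp.vessel_center(m)
        vel = np.zeros((grid, grid))
        # put all flow in one pixel exactly 0.25*D_eq to the right of center
        px = int(round(vc[0] + 0.25 * d_eq))
        vel[int(vc[1]), px] = 100.0
        fd, angle = disp.flow_displacement_frame(vel, m, (1.0, 1.0), +1)
        expected = 100.0 * (px - vc[0]) / d_eq
        assert fd == pytest.approx(expected, abs=1e-9)
        assert angle == pytest.approx(90.0)  # jet pointing image-right

    def test_matches_bruteforce_on_random_fields(self, rng):
        m = disc_mask(32, 12.0)
        for _ in range(10):
            vel = np.where(m, rng.normal(5, 20, (32, 32)), 0.0)
            fd, _ = disp.flow_displacement_frame(vel, m, (0.7, 1.3), +1)
            assert fd == pytest.approx(brute_force_fd(vel, m, (0.7, 1.3), +1), abs=1e-9)

    def test_invariance_to_scaling_and_translation(self, rng):
        m = disc_mask(40, 13.0)
        vel = np.where(m, rng.uniform(0, 30, (40, 40)), 0.0)
        fd0, a0 = disp.flow_displacement_frame(vel, m, (1.0, 1.0), +1)
        fd1, a1 = disp.flow_displacement_frame(3.7 * vel, m, (1.0, 1.0), +1)
        assert (fd1, a1) == pytest.approx((fd0, a0), rel=1e-12)
        shifted_v = np.roll(np.roll(vel, 3, axis=0), 5, axis=1)
        shifted_m = np.roll(np.roll(m, 3, axis=0), 5, axis=1)
        fd2, a2 = disp.flow_displacement_frame(shifted_v, shifted_m, (1.0, 1.0), +1)
        assert (fd2, a2) == pytest.approx((fd0, a0), abs=1e-9)

    def test_boundedness(self, rng):
        m = disc_mask(32, 10.0)
        ys, xs = np.nonzero(m)
        vc = disp.vessel_center(m)
        r_max = np.max(np.hypot(xs - vc[0], ys - vc[1]))
        d_eq = equivalent_diameter_mm(m.sum() * 1.0)
        for _ in range(20):
            vel = np.where(m, rng.normal(0, 10, (32, 32)), 0.0)
            fd, _ = disp.flow_displacement_frame(vel, m, (1.0, 1.0), +1)
            if not math.isnan(fd):
                assert fd <= 100.0 * r_max / d_eq + 1e-9


class TestSummaries:
    def lm(self, peak, end, n):
        return afflow.PhaseLandmarks(peak, end, 0.0, (0, end), (peak, end), (end + 1, n - 1))

    def test_constant_fd(self):
        fds = disp.FDSeries(fd=np.full(10, 20.0), angle=np.zeros(10), gated=np.zeros(10, bool))
        out = disp.fd_summaries(fds, self.lm(3, 5, 10))
        assert all(out[k] == pytest.approx(20.0) for k in ("fds_avg", "fdls_avg", "fdd_avg", "fdps"))

    def test_window_means(self):
        fds = disp.FDSeries(
            fd=np.array([10.0, 10, 30, 30]), angle=np.zeros(4), gated=np.zeros(4, bool)
        )
        out = disp.fd_summaries(fds, afflow.PhaseLandmarks(1, 3, 0.0, (0, 3), (2, 3), None))
        assert out["fdls_avg"] == pytest.approx(30.0)
        assert out["fds_avg"] == pytest.approx(20.0)
        assert out["fdd_avg"] is None
        assert out["fdps"] == pytest.approx(10.0)

    def test_piecewise_profile_hand_means(self):
        fd = np.array([5.0, 15, 25, 35, 20, 10, 8, 8, 8, 8])
        fds = disp.FDSeries(fd=fd, angle=np.zeros(10), gated=np.zeros(10, bool))
        out = disp.fd_summaries(fds, self.lm(3, 5, 10))
        assert out["fds_avg"] == pytest.approx(fd[:6].mean())
        assert out["fdls_avg"] == pytest.approx(fd[3:6].mean())
        assert out["fdd_avg"] == pytest.approx(fd[6:].mean())
        assert out["fdps"] == pytest.approx(35.0)


class TestGating:
    def test_low_fd_gets_zero_angle_and_flag(self):
        fds = disp.FDSeries(
            fd=np.array([10.0, 13.0, 12.0]),
            angle=np.array([45.0, 60.0, 75.0]),
            gated=np.zeros(3, bool),
        )
        out = disp.rotational_angle_series(fds)
        assert out.gated.tolist() == [True, False, True]  # gate is fd <= 12
        assert out.angle.tolist() == [0.0, 60.0, 0.0]

    def test_gate_monotonicity(self, rng):
        fd = rng.uniform(0, 30, 50)
        fds = disp.FDSeries(fd=fd, angle=rng.uniform(-180, 180, 50), gated=np.zeros(50, bool))
        counts = [disp.rotational_angle_series(fds, gate=g).gated.sum() for g in np.linspace(0, 30, 31)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_fixed_jet_along_reference_axis_has_zero_angle(self):
        p = JetParams(offset_fraction=0.20, offset_angle_deg=0.0)
        series, masks, _ = simulate_velocity_series(p)
        fds = disp.compute_fd_series(series, masks)
        ok = ~np.isnan(fds.fd)
        assert np.all(np.abs(fds.angle[ok]) < 1.0)


class TestRotation:
    def lm(self, peak, end, n):
        return afflow.PhaseLandmarks(peak, end, 0.0, (0, end), (peak, end), (end + 1, n - 1))

    def series(self, angles, fd=20.0):
        n = len(angles)
        return disp.FDSeries(
            fd=np.full(n, fd), angle=np.asarray(angles, float), gated=np.zeros(n, bool)
        )

    def test_delta_ra_constant_after_peak_is_zero(self):
        ra = self.series([0, 30, 50, 50, 50, 50, 50, 50])
        assert disp.delta_ra(ra, self.lm(2, 7, 8)) == pytest.approx(0.0)

    def test_delta_ra_subtraction(self):
        # stabilizes at 10 deg then drifts slowly to 40 at end systole
        ra = self.series([0, 80, 10, 12, 14, 22, 31, 40])
        out = disp.delta_ra(ra, self.lm(1, 7, 8))
        assert out == pytest.approx(40.0 - 10.0)

    def test_delta_ra_missing_when_never_stable(self):
        ra = self.series([0, 10, 60, 120, 175, -130, -80, -20])
        with pytest.warns(UserWarning):
            assert disp.delta_ra(ra, self.lm(1, 7, 8), stabilization_threshold_deg=5.0) is None

    def test_unit_conversion(self):
        ra = self.series([0.0, 36.0])
        rot = disp.rotational_speed(ra, self.lm(0, 1, 2), frame_dt=0.1)
        assert rot.rs_series[0] == pytest.approx(1.0)

    def test_constant_angle_zero_speed(self):
        ra = self.series([25.0] * 8)
        rot = disp.rotational_speed(ra, self.lm(2, 6, 8), frame_dt=0.05)
        assert rot.rsls_avg == pytest.approx(0.0)

    def test_gated_pairs_excluded_not_zero_filled(self):
        ra = disp.FDSeries(
            fd=np.array([20.0, 5.0, 20.0, 20.0]),
            angle=np.array([0.0, 0.0, 40.0, 80.0]),
            gated=np.array([False, True, False, False]),
        )
        rot = disp.rotational_speed(ra, self.lm(0, 3, 4), frame_dt=0.1)
        assert np.isnan(rot.rs_series[0]) and np.isnan(rot.rs_series[1])
        assert rot.rs_series[2] == pytest.approx(40.0 / 36.0)
        assert rot.rsls_avg == pytest.approx(40.0 / 36.0)  # mean of eligible pairs only

    def test_wrap_equivalence(self):
        base = [0, 40, 80, 120, 160, -160, -120, -80]
        ra1 = self.series(base)
        ra2 = self.series([a + 360.0 for a in base])
        lm = self.lm(1, 7, 8)
        r1 = disp.rotational_speed(ra1, lm, 0.05)
        r2 = disp.rotational_speed(ra2, lm, 0.05)
        np.testing.assert_allclose(r1.rs_series, r2.rs_series)
        assert disp.delta_ra(ra1, lm) == pytest.approx(disp.delta_ra(ra2, lm))

    def test_scripted_rotation_recovered_from_images(self):
        p = rotating_offset_trajectory(
            JetParams(), fraction=0.20, rotation_rev_s=0.5, window="all", start_angle_deg=20.0
        )
        series, masks, gt = simulate_velocity_series(p)
        fds = disp.compute_fd_series(series, masks)
        ok = ~np.isnan(fds.fd)
        measured = fds.angle[ok]
        imposed = np.array([disp.wrap_angle(a) for a in gt.angle_deg[ok]])
        diff = np.abs([disp.wrap_angle(m - i) for m, i in zip(measured, imposed)])
        assert np.all(diff < 2.0)

    def test_delta_ra_scripted_trajectory(self):
        # rotation only after peak: dRA should match the scripted change
        curve_angles = [0, 0, 0, 0, 0, 0, 5, 9, 12, 14] + [14] * 20
        p = JetParams(offset_fraction=0.20, offset_angle_deg=np.array(curve_angles, float))
        series, masks, gt = simulate_velocity_series(p)
        from aortaflow.flow import compute_flow_curve, detect_phase_landmarks

        lm = detect_phase_landmarks(compute_flow_curve(series, masks))
        fds = disp.rotational_angle_series(disp.compute_fd_series(series, masks))
        got = disp.delta_ra(fds, lm)
        expected = curve_angles[lm.end_systole_idx] - curve_angles[lm.peak_systole_idx + 1]
        assert got == pytest.approx(expected, abs=2.0)
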