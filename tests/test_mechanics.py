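"""Whisker geometry and mechanics: curvature, forces, acceleration, push angle."""

import numpy as np
import pytest

from whiskerglm import mechanics as mech
from whiskerglm.mechanics import (
    BezierCurve,
    DegenerateCurveError,
    NoContactError,
    angle_at_base,
    angular_acceleration,
    contact_forces,
    contact_point,
    curvature_at_base,
    curvature_change,
    push_angle,
    touch_episodes,
)


def fd_curvature_at_base(curve: BezierCurve, h: float = 1e-3) -> float:
    """Independent finite-difference curvature oracle at s = 0.

    One-sided stencils exact for quadratics: x' from (-3, 4, -1)/(2h),
    x'' from (2, -5, 4, -1)/h^2.
    """
    s = np.array([0.0, h, 2 * h, 3 * h])
    p = curve.point(s)
    d1 = (-3 * p[0] + 4 * p[1] - p[2]) / (2 * h)
    d2 = (2 * p[0] - 5 * p[1] + 4 * p[2] - p[3]) / h**2
    return (d1[0] * d2[1] - d2[0] * d1[1]) / (d1 @ d1) ** 1.5


def random_curve(rng) -> BezierCurve:
    while True:
        pts = rng.normal(scale=5.0, size=(3, 2))
        if np.hypot(*(pts[1] - pts[0])) > 0.3:
            return BezierCurve(pts)


class TestCurvature:
    def test_collinear_points_give_zero(self):
        c = BezierCurve([(0, 0), (1, 1), (2, 2)])
        assert curvature_at_base(c) == pytest.approx(0.0, abs=1e-14)

    def test_reference_right_angle_curve(self):
        # exact value 0.5 mm^-1, confirmed by the finite-difference oracle
        c = BezierCurve([(0, 0), (1, 0), (1, 1)])
        assert curvature_at_base(c) == pytest.approx(0.5, rel=1e-12)
        assert curvature_at_base(c) == pytest.approx(fd_curvature_at_base(c), rel=1e-9)

    def test_scaling_inverts_curvature(self, rng):
        c = random_curve(rng)
        scaled = BezierCurve(c.control_points * 3.0)
        assert curvature_at_base(scaled) == pytest.approx(curvature_at_base(c) / 3.0, rel=1e-12)

    def test_matches_finite_difference_oracle_on_random_curves(self, rng):
        for _ in range(100):
            c = random_curve(rng)
            kappa = curvature_at_base(c)
            oracle = fd_curvature_at_base(c)
            assert kappa == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_rotation_invariance(self, rng):
        c = random_curve(rng)
        th = np.radians(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = BezierCurve(c.control_points @ R.T)
        assert curvature_at_base(rotated) == pytest.approx(curvature_at_base(c), rel=1e-10)

    def test_degenerate_curve_raises(self):
        with pytest.raises(DegenerateCurveError):
            curvature_at_base(BezierCurve([(0, 0), (0, 0), (1, 1)]))


class TestAngleAtBase:
    def test_cardinal_directions(self):
        assert angle_at_base(BezierCurve([(0, 0), (1, 0), (2, 0.5)])) == pytest.approx(0.0)
        assert angle_at_base(BezierCurve([(0, 0), (0, 1), (0.5, 2)])) == pytest.approx(90.0)

    def test_rotation_shifts_angle_exactly(self, rng):
        c = random_curve(rng)
        th = np.radians(17.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        base = c.control_points[0]
        rotated = BezierCurve((c.control_points - base) @ R.T + base)
        delta = angle_at_base(rotated) - angle_at_base(c)
        assert (delta + 180) % 360 - 180 == pytest.approx(17.0, abs=1e-9)


class TestCurvatureChange:
    def test_constant_series_gives_zero(self):
        dk = curvature_change(np.full(500, 0.3), [(0, 500)])
        assert np.allclose(dk, 0.0)

    def test_step_after_intrinsic_window(self):
        kappa = np.concatenate([np.full(100, 0.1), np.full(400, 0.15)])
        dk = curvature_change(kappa, [(0, 500)])
        assert np.allclose(dk[:100], 0.0)
        assert np.allclose(dk[100:], 0.05)

    def test_window_mean_matches_brute_force(self, rng):
        kappa = rng.normal(size=900)
        bounds = [(0, 300), (300, 900)]
        dk = curvature_change(kappa, bounds)
        for start, stop in bounds:
            expected = kappa[start:stop] - np.mean([kappa[start + i] for i in range(100)])
            assert np.allclose(dk[start:stop], expected)

    def test_short_trial_raises(self):
        with pytest.raises(ValueError):
            curvature_change(np.zeros(90), [(0, 90)])


class TestContactForces:
    def test_zero_moment_gives_zero_forces(self):
        g = contact_forces(0.0, 2.0, 0.5, 0.3, 0.1)
        assert g.F == 0 and g.F_ax == 0 and g.F_lat == 0

    def test_aligned_tangents_give_pure_lateral(self):
        g = contact_forces(1.0, 2.0, np.pi / 2, 0.7, 0.7)
        assert g.F_ax == pytest.approx(0.0)
        assert g.F_lat == pytest.approx(g.F)

    def test_reference_values(self):
        # F = M/(r sin phi) = 2/(4 * 0.5) = 1; theta difference 90 deg
        g = contact_forces(2.0, 4.0, np.radians(30), np.radians(90), 0.0)
        assert g.F == pytest.approx(1.0)
        assert g.F_ax == pytest.approx(1.0)
        assert g.F_lat == pytest.approx(0.0, abs=1e-12)

    def test_pythagorean_and_moment_identities(self, rng):
        M = rng.normal(size=10_000)
        r = rng.uniform(0.1, 20, size=10_000)
        phi = rng.uniform(0.05, np.pi - 0.05, size=10_000)
        tb = rng.uniform(-np.pi, np.pi, size=10_000)
        tc = rng.uniform(-np.pi, np.pi, size=10_000)
        g = contact_forces(M, r, phi, tb, tc)
        np.testing.assert_allclose(g.F_ax**2 + g.F_lat**2, g.F**2, rtol=1e-12)
        np.testing.assert_allclose(g.F * g.r * np.sin(g.phi), g.M, rtol=1e-12)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            contact_forces(1.0, -1.0, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            contact_forces(1.0, 1.0, 0.0, 0.0, 0.0)


class TestContactPoint:
    def test_straight_whisker_through_pole_center(self):
        c = BezierCurve([(0, 0), (5, 0), (10, 0)])
        res = contact_point(c, (4.0, 0.0), pole_radius=0.25)
        assert res["distance"] == pytest.approx(0.0, abs=1e-9)
        assert res["point"][0] == pytest.approx(4.0, abs=1e-9)
        assert res["r"] == pytest.approx(4.0, abs=1e-9)

    def test_far_pole_is_no_contact(self):
        c = BezierCurve([(0, 0), (5, 0), (10, 0)])
        with pytest.raises(NoContactError):
            contact_point(c, (4.0, 30.0), pole_radius=0.25)

    def test_minimizer_matches_grid_search(self, rng):
        for _ in range(20):
            c = random_curve(rng)
            target = c.point(rng.uniform(0.2, 0.8)) + rng.normal(scale=0.1, size=2)
            res = contact_point(c, target, pole_radius=5.0)
            s_grid = np.linspace(0, 1, 100_001)
            pts = c.point(s_grid)
            d = np.hypot(pts[:, 0] - target[0], pts[:, 1] - target[1])
            s_star = s_grid[np.argmin(d)]
            assert abs(res["s"] - s_star) < 1e-4

    def test_tip_contact_flagged(self):
        c = BezierCurve([(0, 0), (5, 0), (10, 0)])
        with pytest.warns(RuntimeWarning, match="distal end"):
            res = contact_point(c, (12.0, 0.0), pole_radius=0.25, tol=5.0)
        assert res["at_endpoint"]


class TestAngularAcceleration:
    def test_constant_angle_gives_zero(self):
        acc = angular_acceleration(np.full(200, 12.0))
        # zero up to float rounding of the smoother amplified by fs^2 (~1e-5),
        # negligible against physiological accelerations of order 1e4 deg/s^2
        assert np.allclose(acc, 0.0, atol=1e-3)

    def test_quadratic_angle_recovers_constant_acceleration(self):
        t = np.arange(500) / 1000.0
        a_true = 4000.0  # deg/s^2
        acc = angular_acceleration(0.5 * a_true * t**2)
        assert np.allclose(acc[20:-20], a_true, rtol=1e-9)

    def test_sinusoid_matches_analytic_second_derivative(self):
        t = np.arange(2000) / 1000.0
        f, A = 10.0, 8.0
        acc = angular_acceleration(A * np.sin(2 * np.pi * f * t))
        expected = -A * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        interior = slice(30, -30)
        err = np.abs(acc[interior] - expected[interior]) / (A * (2 * np.pi * f) ** 2)
        assert err.max() < 0.02

    def test_operator_is_linear(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        lhs = angular_acceleration(2.0 * x + 3.0 * y)
        rhs = 2.0 * angular_acceleration(x) + 3.0 * angular_acceleration(y)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_strategies_agree_on_whisking_band_signal(self):
        t = np.arange(1000) / 1000.0
        x = 8 * np.sin(2 * np.pi * 10 * t) + 3 * np.sin(2 * np.pi * 25 * t + 1.0)
        a1 = angular_acceleration(x, strategy="smooth_diff")
        a2 = angular_acceleration(x, strategy="sg_derivative")
        corr = np.corrcoef(a1[50:-50], a2[50:-50])[0, 1]
        assert corr > 0.999

    def test_invalid_filter_spec_raises(self):
        with pytest.raises(ValueError):
            angular_acceleration(np.zeros(100), frame_ms=30)  # even frame
        with pytest.raises(ValueError):
            angular_acceleration(np.zeros(100), poly_order=5, frame_ms=5)


class TestPushAngle:
    def test_flat_angle_gives_zero_push(self):
        pa = push_angle(np.full(100, 10.0), [(20, 50)])
        assert np.allclose(pa[20:50], 0.0)
        assert np.isnan(pa[:20]).all() and np.isnan(pa[50:]).all()

    def test_ramp_reaches_five_degrees(self):
        angle = np.concatenate([np.full(20, 10.0), np.linspace(10, 15, 30)])
        pa = push_angle(angle, [(20, 50)])
        assert pa[49] == pytest.approx(5.0)

    def test_each_episode_uses_its_own_reference(self, rng):
        angle = rng.normal(size=200)
        mask = np.zeros(200, dtype=int)
        mask[30:60] = 1
        mask[100:140] = 1
        pa = push_angle(angle, mask)
        assert np.allclose(pa[30:60], angle[30:60] - angle[29])
        assert np.allclose(pa[100:140], angle[100:140] - angle[99])

    def test_episode_at_bin_zero_flagged(self):
        with pytest.warns(RuntimeWarning, match="no pre-onset"):
            pa = push_angle(np.arange(50.0), [(0, 10)])
        assert np.isnan(pa[:10]).all()


def test_touch_episodes_roundtrip():
    mask = np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 1])
    assert touch_episodes(mask) == [(1, 3), (5, 6), (7, 10)]
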