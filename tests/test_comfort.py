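"""Bell-shaped comfort function: boundary constraints and shape."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from scrubcomfort import ComfortParams, ScrubCondition
from scrubcomfort.comfort import (
    SIGMA,
    bell_center,
    comfort_from_condition,
    comfort_function,
    comfort_gaussian,
    comfort_surface,
    peak_magnitude,
)

shape_a = st.floats(0.7, 3.0)
shape_b = st.floats(0.6, 4.0)


class TestComfortGaussian:
    def test_peak_is_one_with_model_sigma(self):
        assert comfort_gaussian(0.3, sigma=SIGMA, center=0.3) == pytest.approx(1.0, abs=1e-15)

    def test_standard_normal_peak(self):
        assert comfort_gaussian(0.0, sigma=1.0, center=0.0) == pytest.approx(
            1 / math.sqrt(2 * math.pi), abs=1e-12
        )

    def test_symmetry(self):
        assert comfort_gaussian(0.5 + 0.2, center=0.5) == pytest.approx(
            comfort_gaussian(0.5 - 0.2, center=0.5), abs=1e-15
        )


class TestComfortFunction:
    @given(shape_a, shape_b)
    @settings(deadline=None)
    def test_baseline_is_exactly_half(self, a, b):
        """g(0) = 0.5 for every valid shape pair — the constraint that
        fixes the centre constant."""
        assert comfort_function(0.0, a, b) == pytest.approx(0.5, abs=1e-12)

    @given(shape_a, shape_b)
    @settings(deadline=None)
    def test_peak_is_exactly_one(self, a, b):
        # fractional a < 1 amplifies the float rounding of s_star**b,
        # hence the 1e-9 (rather than machine-level) tolerance
        s_star = peak_magnitude(a, b)
        assert comfort_function(s_star, a, b) == pytest.approx(1.0, abs=1e-9)

    def test_peak_location_closed_form_vs_numeric(self):
        """Dense grid + bounded refinement agrees with the closed-form
        argmax S* = (ln2/pi)^(1/(a*b)); the maximum value is 1."""
        a, b = 1.04, 2.01
        s_star = peak_magnitude(a, b)
        grid = np.linspace(0.0, 3.0, 20001)
        vals = comfort_function(grid, a, b)
        s0 = grid[np.argmax(vals)]
        res = minimize_scalar(lambda s: -comfort_function(s, a, b),
                              bounds=(max(s0 - 1e-3, 0.0), s0 + 1e-3), method="bounded",
                              options={"xatol": 1e-12})
        assert res.x == pytest.approx(s_star, abs=1e-6)
        assert -res.fun == pytest.approx(1.0, abs=1e-8)
        assert comfort_function(s_star, a, b) == pytest.approx(1.0, abs=1e-12)

    def test_far_tail_decays_to_zero(self):
        assert comfort_function(10.0, 1.04, 2.01) < 1e-10

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            comfort_function(-0.1, 1.04, 2.01)

    def test_bounded_between_zero_and_one(self):
        S = np.linspace(0.0, 5.0, 1000)
        g = comfort_function(S, 1.04, 2.01)
        assert np.all(g > 0) and np.all(g <= 1.0)

    def test_gaussian_special_case(self):
        """With a = 2, b = 1 the comfort curve is a Gaussian with
        sigma = 1/sqrt(2*pi), rescaled to peak at 1."""
        S = np.linspace(0.0, 2.0, 500)
        mu_p = bell_center(2.0)
        lhs = comfort_function(S, a=2.0, b=1.0)
        rhs = comfort_gaussian(S, sigma=SIGMA, center=mu_p) * SIGMA * math.sqrt(2 * math.pi)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_monotone_in_distance_from_peak(self):
        a, b = 1.04, 2.01
        mu_p = bell_center(a)
        S = np.linspace(0.0, 3.0, 2000)
        dist = np.abs(S**b - mu_p)
        g = comfort_function(S, a, b)
        order = np.argsort(dist)
        assert np.all(np.diff(g[order]) <= 1e-12)


class TestComfortFromCondition:
    def test_zero_condition_is_neutral(self, calibrated_params):
        cond = ScrubCondition(v=0.0, N=0.0, dt=10.0)
        assert comfort_from_condition(cond, calibrated_params) == pytest.approx(0.5, abs=1e-12)

    def test_ridge_point_reaches_full_comfort(self, calibrated_params):
        """Solving S(v, N) = S* for N at v = 0.04 m/s gives a condition
        with comfort exactly 1."""
        s_star = calibrated_params.s_peak
        v, dt = 0.04, 10.0
        N = (s_star / (calibrated_params.c0 * v**calibrated_params.x * dt**calibrated_params.n)) ** (
            1.0 / (calibrated_params.m_exp * calibrated_params.y)
        )
        assert N == pytest.approx(1.8956, abs=2e-3)
        cond = ScrubCondition(v=v, N=N, dt=dt)
        assert comfort_from_condition(cond, calibrated_params) == pytest.approx(1.0, abs=1e-12)

    def test_unimodal_along_increasing_ray(self, calibrated_params):
        """Comfort along a ray of jointly increasing (v, N) rises to the
        peak then falls: one sign change in the differences."""
        t = np.linspace(0.01, 1.0, 300)
        g = comfort_surface(0.05 * t, 3.0 * t, 10.0, calibrated_params)
        d = np.sign(np.diff(g))
        changes = np.sum(np.abs(np.diff(d[d != 0])) > 0)
        assert changes <= 1

    def test_surface_matches_scalar_path(self, calibrated_params):
        v, N = 0.035, 1.2
        scalar = comfort_from_condition(ScrubCondition(v=v, N=N, dt=10.0), calibrated_params)
        vect = comfort_surface(np.array([v]), np.array([N]), 10.0, calibrated_params)[0]
        assert scalar == pytest.approx(vect, abs=1e-15)


class TestComfortParams:
    def test_derived_constants(self, calibrated_params):
        assert calibrated_params.sigma == pytest.approx(1 / math.sqrt(2 * math.pi))
        assert calibrated_params.center == pytest.approx((math.log(2) / math.pi) ** (1 / 1.04))
        assert calibrated_params.s_peak == pytest.approx(
            (math.log(2) / math.pi) ** (1 / (1.04 * 2.01))
        )
        assert 0 < calibrated_params.center < 1

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ComfortParams(a=-1.0)
        with pytest.raises(ValueError):
            ComfortParams(mu=1.2)
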