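"""Friction and deformation energy model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrubcomfort.energy import (
    ScrubCondition,
    SkinProperties,
    deformation_energies,
    friction_force,
    rotational_energy_per_rev,
    total_energy_full,
    total_energy_simplified,
)


class TestFrictionForce:
    @pytest.mark.parametrize(
        "N, expected",
        [
            (1.0, 0.25),          # unit load: f = mu
            (2.0, 0.25 * 2**0.7),  # = 0.40613
            (0.0, 0.0),
        ],
    )
    def test_power_law_values(self, N, expected):
        assert friction_force(N, mu=0.25, m_exp=0.7) == pytest.approx(expected, rel=1e-12)

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            friction_force(-1.0)

    @given(st.floats(0.01, 20.0), st.floats(0.01, 20.0))
    @settings(deadline=None)
    def test_sublinear_in_load(self, n1, n2):
        """With m < 1 the force ratio is compressed relative to the load ratio."""
        lo, hi = sorted([n1, n2])
        if hi / lo < 1.001:
            return
        ratio = friction_force(hi) / friction_force(lo)
        assert ratio == pytest.approx((hi / lo) ** 0.7, rel=1e-9)


class TestRotationalEnergy:
    @pytest.mark.parametrize(
        "f, r, expected",
        [
            (0.25, 0.05, (4 / 3) * math.pi * 0.25 * 0.05),  # 0.05236 J
            (0.0, 0.05, 0.0),
            (3 / (4 * math.pi), 1.0, 1.0),
        ],
    )
    def test_per_revolution(self, f, r, expected):
        assert rotational_energy_per_rev(f, r) == pytest.approx(expected, rel=1e-12)


class TestDeformationEnergies:
    def test_normal_deformation(self):
        skin = SkinProperties(l=0.008, Y1=1e5, Y2=5e4, A=7.85e-3)
        e_sigma, _ = deformation_energies(N=1.0, f=0.25, skin=skin)
        assert e_sigma == pytest.approx(1.0 * 0.008 / (2 * 1e5 * 7.85e-3), rel=1e-12)
        assert e_sigma == pytest.approx(5.096e-6, rel=1e-3)

    def test_tangential_deformation(self):
        skin = SkinProperties(l=0.008, Y1=1e5, Y2=5e4, A=7.85e-3)
        _, e_tau = deformation_energies(N=1.0, f=0.25, skin=skin)
        assert e_tau == pytest.approx(0.0625 * 0.008 / (7.85e-3 * 5e4), rel=1e-12)
        assert e_tau == pytest.approx(1.274e-6, rel=1e-3)

    def test_zero_forces(self):
        assert deformation_energies(0.0, 0.0, SkinProperties()) == (0.0, 0.0)

    def test_invalid_skin_rejected(self):
        with pytest.raises(ValueError):
            SkinProperties(A=0.0)


class TestTotalEnergy:
    def test_no_rotation_drops_rotational_term(self):
        cond = ScrubCondition(v=0.03, N=1.0, dt=10.0, omega=0.0)
        bd = total_energy_full(cond)
        assert bd.Er == 0.0
        assert bd.E == pytest.approx(bd.Et + bd.Esigma + bd.Etau)

    def test_matched_rim_speed(self):
        """With r*omega = v, friction energy is (v + 2v/3)*f*dt."""
        cond = ScrubCondition(v=0.03, N=1.0, dt=10.0, omega=0.03 / 0.05)
        bd = total_energy_full(cond)
        assert bd.Ef == pytest.approx(0.05 * 0.25 * 10.0, rel=1e-12)  # 0.125 J

    def test_skin_terms_match_deformation_energies(self):
        skin = SkinProperties(l=0.008, Y1=1e5, Y2=5e4, A=7.85e-3)
        cond = ScrubCondition(v=0.03, N=2.0, dt=10.0)
        bd = total_energy_full(cond, skin)
        f = friction_force(2.0)
        assert (bd.Esigma, bd.Etau) == deformation_energies(2.0, f, skin)

    @pytest.mark.parametrize(
        "v, N, dt, expected",
        [
            (0.03, 1.0, 10.0, 0.1),  # (4/3)*0.03*0.25*10
            (0.0, 1.0, 10.0, 0.0),
        ],
    )
    def test_simplified_values(self, v, N, dt, expected):
        cond = ScrubCondition(v=v, N=N, dt=dt)
        assert total_energy_simplified(cond) == pytest.approx(expected, rel=1e-12)

    def test_full_reduces_to_simplified(self, rng):
        """Oracle: with rim speed = v and zero-thickness skin, the full
        budget equals (5/3)*v*f*dt, and dropping the rotational term's
        2/3 share reproduces the simplified (4/3)*v*f*dt formula."""
        thin = SkinProperties(l=1e-300, Y1=1e5, Y2=5e4, A=7.85e-3)
        for _ in range(100):
            v = rng.uniform(0.001, 0.1)
            N = rng.uniform(0.1, 6.0)
            dt = rng.uniform(1.0, 30.0)
            cond = ScrubCondition(v=v, N=N, dt=dt)
            f = friction_force(N)
            bd = total_energy_full(cond, thin)
            assert bd.E == pytest.approx((v + 2 * v / 3) * f * dt, rel=1e-12)
            assert total_energy_simplified(cond) == pytest.approx(
                (4 / 3) * v * f * dt, rel=1e-12
            )

    def test_monotone_in_each_argument(self):
        base = dict(v=0.03, N=1.5, dt=10.0)
        e0 = total_energy_simplified(ScrubCondition(**base))
        for key, bump in [("v", 0.01), ("N", 0.5), ("dt", 5.0)]:
            kwargs = dict(base)
            kwargs[key] += bump
            assert total_energy_simplified(ScrubCondition(**kwargs)) > e0

    def test_scaling_exponents_by_log_slope(self):
        """Simplified energy is linear in v and dt and scales as N^0.7."""
        grid = np.linspace(1.0, 4.0, 8)

        def log_slope(values, energies):
            slope, _ = np.polyfit(np.log(values), np.log(energies), 1)
            return slope

        ev = [total_energy_simplified(ScrubCondition(v=0.01 * g, N=1.5, dt=10)) for g in grid]
        en = [total_energy_simplified(ScrubCondition(v=0.03, N=g, dt=10)) for g in grid]
        et = [total_energy_simplified(ScrubCondition(v=0.03, N=1.5, dt=5 * g)) for g in grid]
        assert log_slope(0.01 * grid, ev) == pytest.approx(1.0, abs=1e-10)
        assert log_slope(grid, en) == pytest.approx(0.7, abs=1e-10)
        assert log_slope(5 * grid, et) == pytest.approx(1.0, abs=1e-10)


class TestScrubCondition:
    def test_mm_s_conversion_round_trip(self):
        cond = ScrubCondition.from_mm_s(36.47, 1.68, 10.0)
        assert cond.v == pytest.approx(0.03647)
        assert cond.v_mm_s == pytest.approx(36.47)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(v=-0.01, N=1.0, dt=10.0),
            dict(v=0.03, N=-1.0, dt=10.0),
            dict(v=0.03, N=1.0, dt=0.0),
            dict(v=0.03, N=1.0, dt=10.0, mu=1.5),
            dict(v=0.03, N=1.0, dt=10.0, r=0.0),
        ],
    )
    def test_invalid_conditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScrubCondition(**kwargs)
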