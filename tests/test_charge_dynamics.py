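import math

import mpmath
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from prestinmem.charge_dynamics import (
    charge_from_loading_convolution,
    charge_ramp_pressure,
    charge_ramp_strain,
    charge_step_pressure,
    circumferential_rate,
    generalized_expint,
    pressure_coupling,
    pressure_resultants,
    resultant_rates_from_strain,
)
from prestinmem.parameters import LoadingHistory


class TestResultants:
    def test_cylinder_resultants(self, ohc):
        N = pressure_resultants(ohc, 200.0)
        assert N[0] == pytest.approx(200.0 * ohc.r_c / 2.0)
        assert N[1] == pytest.approx(200.0 * ohc.r_c)

    def test_sphere_resultant(self, sphere):
        N = pressure_resultants(sphere, 200.0)
        assert N.shape == (1,)
        assert N[0] == pytest.approx(200.0 * sphere.r_c / 2.0)


class TestStepPressure:
    def test_zero_pressure_zero_charge(self, ohc, t_grid):
        assert np.all(charge_step_pressure(ohc, 0.0, t_grid).q == 0.0)

    def test_rc_time_course(self, ohc, t_grid):
        tc = charge_step_pressure(ohc, 150.0, t_grid)
        q_inf = pressure_coupling(ohc) * 150.0
        assert np.allclose(tc.q / q_inf, 1.0 - np.exp(-t_grid / ohc.tau_e), rtol=1e-12)

    def test_convolution_oracle(self, ohc, t_grid):
        tc = charge_step_pressure(ohc, 150.0, t_grid)
        oracle = charge_from_loading_convolution(
            ohc, LoadingHistory("step_pressure", dP0=150.0), t_grid
        )
        assert np.allclose(tc.q, oracle.q, rtol=1e-6)

    def test_sphere_charge_exceeds_cylinder_at_equal_radius(self, ohc, sphere, t_grid):
        assert sphere.r_c == ohc.r_c
        q_cyl = charge_step_pressure(ohc, 100.0, t_grid).q
        q_sph = charge_step_pressure(sphere, 100.0, t_grid).q
        assert np.all(np.abs(q_sph) > np.abs(q_cyl))

    def test_positive_pressure_negative_charge(self, ohc, sphere, t_grid):
        assert np.all(charge_step_pressure(ohc, 100.0, t_grid).q < 0)
        assert np.all(charge_step_pressure(sphere, 100.0, t_grid).q < 0)

    @given(scale=st.floats(0.1, 50.0))
    def test_linearity_in_dP0(self, ohc, t_grid, scale):
        base = charge_step_pressure(ohc, 100.0, t_grid).q
        scaled = charge_step_pressure(ohc, 100.0 * scale, t_grid).q
        assert np.allclose(scaled, base * scale, rtol=1e-12)

    def test_vanishes_at_early_time(self, ohc):
        q = charge_step_pressure(ohc, 100.0, np.array([1e-12])).q
        assert abs(q[0]) < 1e-6 * abs(pressure_coupling(ohc) * 100.0)


class TestRampPressure:
    def test_zero_rate_zero_charge(self, ohc, t_grid):
        assert np.all(charge_ramp_pressure(ohc, 0.0, t_grid).q == 0.0)

    def test_long_time_slope_matches_step_steady_state(self, ohc):
        # Duhamel: dq/dt at 20 tau_e -> P_r * q_step(inf)/dP0
        P_r = 2e7
        t0 = 20 * ohc.tau_e
        h = 1e-9
        t = np.array([t0 - h, t0 + h])
        q = charge_ramp_pressure(ohc, P_r, t).q
        slope = (q[1] - q[0]) / (2 * h)
        expected = P_r * pressure_coupling(ohc)
        assert slope == pytest.approx(expected, rel=1e-4)

    def test_duhamel_superposition_integral_of_steps(self, ohc):
        # q_ramp(t) = (P_r/dP0) * int_0^t q_step(s) ds
        P_r, dP0 = 5e6, 100.0
        t_end = 3e-5
        val, _ = integrate.quad(
            lambda s: charge_step_pressure(ohc, dP0, np.array([s])).q[0],
            0.0,
            t_end,
            limit=200,
        )
        q_ramp = charge_ramp_pressure(ohc, P_r, np.array([t_end])).q[0]
        assert q_ramp == pytest.approx(P_r / dP0 * val, rel=1e-4)

    def test_convolution_oracle_both_geometries(self, ohc, sphere, t_grid):
        for params in (ohc, sphere):
            tc = charge_ramp_pressure(params, 1e7, t_grid)
            oracle = charge_from_loading_convolution(
                params, LoadingHistory("ramp_pressure", P_r=1e7), t_grid
            )
            assert np.allclose(tc.q, oracle.q, rtol=1e-6)

    def test_larger_tau_e_smaller_charge(self, ohc, t_grid):
        q_fast = np.abs(charge_ramp_pressure(ohc, 1e7, t_grid).q)
        q_slow = np.abs(charge_ramp_pressure(ohc.replace(tau_e=2e-5), 1e7, t_grid).q)
        assert np.all(q_slow < q_fast)


class TestRampStrain:
    def test_circumferential_rate_volume_conservation(self):
        assert circumferential_rate(-2.0) == pytest.approx(1.0)

    def test_zero_rate_zero_resultants(self, ohc):
        assert np.all(resultant_rates_from_strain(ohc, 0.0, 1e-5) == 0.0)

    def test_elastic_limit_rates_constant(self, ohc):
        p = ohc.replace(eta=0.0)
        r1 = resultant_rates_from_strain(p, -1.0, 1e-6)
        r2 = resultant_rates_from_strain(p, -1.0, 1e-3)
        assert np.allclose(r1, r2)

    def test_rates_domain_error(self, ohc):
        with pytest.raises(ValueError):
            resultant_rates_from_strain(ohc, -1.0, 0.0)

    def test_rates_match_differentiated_resultant_history(self, ohc):
        # finite difference of the convolved (integrated-kernel) history
        eps_rate = -1.0
        t0, h = 8e-6, 1e-9
        from scipy.special import gamma

        def N_of(t):
            eps = np.array([eps_rate, circumferential_rate(eps_rate)])
            visc = ohc.eta * t ** (1 - ohc.nu) / gamma(2 - ohc.nu)
            return (ohc.elastic_matrix * t + visc * np.ones((2, 2))) @ eps

        fd = (N_of(t0 + h) - N_of(t0 - h)) / (2 * h)
        rates = resultant_rates_from_strain(ohc, eps_rate, t0)
        assert np.allclose(rates, fd, rtol=1e-5)

    def test_zero_strain_rate_zero_charge(self, ohc, t_grid):
        assert np.all(charge_ramp_strain(ohc, 0.0, t_grid).q == 0.0)

    def test_compression_gives_positive_charge(self, ohc, t_grid):
        assert np.all(charge_ramp_strain(ohc, -1.0, t_grid).q > 0)

    def test_magnitude_increases_with_power(self, ohc, t_grid):
        mags = []
        for nu in (0.5, 0.7, 0.9):
            q = charge_ramp_strain(ohc.replace(nu=nu), -1.0, t_grid).q
            mags.append(np.abs(q))
        assert np.all(mags[1] > mags[0])
        assert np.all(mags[2] > mags[1])

    def test_convolution_oracle(self, ohc, t_grid):
        tc = charge_ramp_strain(ohc, -1.0, t_grid)
        oracle = charge_from_loading_convolution(
            ohc, LoadingHistory("ramp_strain", eps1_rate=-1.0), t_grid
        )
        rel = np.abs(tc.q - oracle.q).max() / np.abs(tc.q).max()
        assert rel < 1e-3

    @given(scale=st.floats(0.1, 20.0))
    def test_linearity_in_strain_rate(self, ohc, t_grid, scale):
        base = charge_ramp_strain(ohc, -1.0, t_grid).q
        scaled = charge_ramp_strain(ohc, -scale, t_grid).q
        assert np.allclose(scaled, base * scale, rtol=1e-12)

    def test_rejects_sphere(self, sphere, t_grid):
        with pytest.raises(TypeError):
            charge_ramp_strain(sphere, -1.0, t_grid)

    def test_rejects_kelvin_voigt(self, ohc, t_grid):
        with pytest.raises(ValueError):
            charge_ramp_strain(ohc.replace(nu=1.0), -1.0, t_grid)


class TestGeneralizedExpint:
    def test_E1_of_1_quadrature_oracle(self):
        # adaptive quadrature of the defining integral, frozen reference
        val, _ = integrate.quad(lambda u: math.exp(-u) / u, 1.0, np.inf)
        assert val == pytest.approx(0.2193839343955203, rel=1e-10)
        assert generalized_expint(1.0, 1.0) == pytest.approx(val, rel=1e-10)

    @pytest.mark.parametrize("nu,x", [(0.7, 0.5), (0.3, 2.0), (1.7, 0.5), (-0.5, 1.0)])
    def test_defining_integral(self, nu, x):
        val, _ = integrate.quad(lambda u: math.exp(-x * u) * u ** (-nu), 1.0, np.inf)
        assert generalized_expint(nu, x) == pytest.approx(val, rel=1e-10)

    @pytest.mark.parametrize("nu,x", [(0.7, 0.5), (0.3, 3.0), (2.5, 1.0)])
    def test_against_mpmath(self, nu, x):
        with mpmath.workdps(40):
            ref = float(mpmath.expint(nu, x))
        assert generalized_expint(nu, x) == pytest.approx(ref, rel=1e-12)

    def test_recurrence_identity(self):
        nu, x = 0.7, 0.5
        lhs = nu * generalized_expint(nu + 1.0, x)
        rhs = math.exp(-x) - x * generalized_expint(nu, x)
        assert abs(lhs - rhs) < 1e-10

    def test_strictly_decreasing_in_x(self):
        xs = np.linspace(0.1, 5.0, 40)
        vals = [generalized_expint(0.7, x) for x in xs]
        assert np.all(np.diff(vals) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            generalized_expint(0.7, 0.0)
        with pytest.raises(ValueError):
            generalized_expint(0.7, -1.0)


class TestMonotonicityFigures:
    """Qualitative parametric trends of the charge responses."""

    def test_charge_increases_with_pressure(self, ohc, t_grid):
        q1 = np.abs(charge_step_pressure(ohc, 100.0, t_grid).q)
        q2 = np.abs(charge_step_pressure(ohc, 200.0, t_grid).q)
        assert np.all(q2 > q1)

    def test_charge_increases_with_pressure_rate(self, sphere, t_grid):
        q1 = np.abs(charge_ramp_pressure(sphere, 1e6, t_grid).q)
        q2 = np.abs(charge_ramp_pressure(sphere, 3e6, t_grid).q)
        assert np.all(q2 > q1)

    def test_charge_increases_with_strain_rate(self, ohc, t_grid):
        q1 = np.abs(charge_ramp_strain(ohc, -0.5, t_grid).q)
        q2 = np.abs(charge_ramp_strain(ohc, -1.5, t_grid).q)
        assert np.all(q2 > q1)

    def test_ramp_strain_longer_tau_smaller_charge(self, ohc, t_grid):
        q_fast = np.abs(charge_ramp_strain(ohc, -1.0, t_grid).q)
        q_slow = np.abs(charge_ramp_strain(ohc.replace(tau_e=2e-5), -1.0, t_grid).q)
        assert np.all(q_slow < q_fast)
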