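"""Unit tests for the dynamical core."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from erokin import (
    ModelParams,
    PhysicalParams,
    derive_b0_psi,
    front_radius,
    get_preset,
    integrate_rk4,
    omega_p,
    simulate_front,
    smooth_switch,
)
from erokin.kinetics import rhs_mu_s


class TestOmegaP:
    def test_unity_at_time_zero(self):
        assert omega_p(0.0, 0.104) == 1.0

    def test_direct_evaluation(self):
        # independent arithmetic: exp(-0.104 * 10) = exp(-1.04)
        assert omega_p(10.0, 0.104) == pytest.approx(0.35346, abs=1e-5)

    def test_monotone_decay_to_zero(self):
        t = np.linspace(0, 400, 200)
        w = omega_p(t, 0.104)
        assert np.all(np.diff(w) < 0)
        assert w[-1] < 1e-15

    @pytest.mark.parametrize("t,k", [(-1.0, 0.1), (1.0, -0.1)])
    def test_domain_errors(self, t, k):
        with pytest.raises(ValueError):
            omega_p(t, k)


class TestSmoothSwitch:
    def test_half_at_induction_time(self):
        assert smooth_switch(3.42, 3.42, 2.5) == pytest.approx(0.5)

    def test_limits(self):
        assert smooth_switch(100.0, 3.0, 2.5) == pytest.approx(1.0)
        assert smooth_switch(-100.0, 3.0, 2.5) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_time(self):
        t = np.linspace(0, 10, 500)
        s = smooth_switch(t, 3.0, 2.5)
        assert np.all(np.diff(s) >= 0)  # tanh saturates in float at the tails
        assert np.all(np.diff(s)[np.abs(t[:-1] - 3.0) < 2.0] > 0)
        assert np.all((s > 0) & (s <= 1))

    def test_large_alpha_approaches_heaviside(self):
        # pointwise limit away from the switch time
        assert smooth_switch(3.0 - 0.01, 3.0, 1e4) == pytest.approx(0.0, abs=1e-12)
        assert smooth_switch(3.0 + 0.01, 3.0, 1e4) == pytest.approx(1.0, abs=1e-12)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            smooth_switch(1.0, 1.0, 0.0)


class TestRhs:
    def test_vanishes_at_full_erosion(self, preset):
        assert rhs_mu_s(10.0, 1.0, preset.params) == 0.0

    def test_vanishes_for_zero_b0(self):
        p = ModelParams(b0=0.0, psi=1e-5, t_ind=3.0, k_deg=0.1)
        assert rhs_mu_s(10.0, 0.5, p) == 0.0

    def test_plga10_point_value(self):
        # independent arithmetic: 0.0248 * 0.8 / (2.69e-5*exp(-1.04) + 0.8)
        #   * (tanh(2.5 * 6.58) + 1) / 2  ~= 0.02480
        p = get_preset("PLGA10").params
        assert rhs_mu_s(10.0, 0.2, p) == pytest.approx(0.02480, abs=5e-6)

    def test_bounded_by_b0_and_nonnegative(self, preset):
        p = preset.params
        for t in np.linspace(0, 42, 20):
            for mu in np.linspace(0, 1, 11):
                v = rhs_mu_s(float(t), float(mu), p)
                assert 0.0 <= v <= p.b0 + 1e-15

    def test_domain_error_outside_unit_interval(self, plga15):
        with pytest.raises(ValueError):
            rhs_mu_s(1.0, 1.5, plga15.params)


class TestFrontRadius:
    def test_fixed_points(self):
        assert front_radius(0.0) == 0.0
        assert front_radius(1.0) == 1.0

    def test_cube_root_value(self):
        assert front_radius(0.5) == pytest.approx(0.79370, abs=1e-5)

    def test_shell_volume_round_trip(self):
        mu = np.linspace(0, 1, 50)
        assert np.allclose(1.0 - front_radius(mu) ** 3, 1.0 - mu, atol=1e-14)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            front_radius(1.2)


class TestIntegrateRK4:
    def test_zero_b0_stays_at_zero(self):
        p = ModelParams(b0=0.0, psi=1e-5, t_ind=3.0, k_deg=0.1)
        c = integrate_rk4(p, 42.0, 0.05)
        assert np.all(c.mu_s == 0.0)
        assert np.all(c.r_f == 0.0)

    def test_curve_invariants(self, preset):
        c = integrate_rk4(preset.params, 42.0, 0.05)
        assert c.t[0] == 0.0 and c.mu_s[0] == 0.0
        assert np.all(np.diff(c.t) > 0)
        assert np.all(np.diff(c.mu_s) >= 0)
        assert np.all(np.diff(c.r_f) >= 0)
        assert np.all((c.mu_s >= 0) & (c.mu_s <= 1))
        # mass conservation and front identity at machine precision
        assert np.all(c.mu_s + c.mu_p == 1.0)
        np.testing.assert_allclose(c.r_f, np.cbrt(c.mu_s), atol=1e-15)
        assert np.all(np.diff(c.omega_p) < 0)

    def test_long_horizon_approaches_but_never_exceeds_one(self, plga15):
        c = integrate_rk4(plga15.params, 200.0, 0.05)
        assert c.mu_s[-1] <= 1.0
        assert c.mu_s[-1] > 0.999

    def test_self_convergence(self, preset):
        coarse = integrate_rk4(preset.params, 42.0, 0.1)
        fine = integrate_rk4(preset.params, 42.0, 0.001)
        interp = np.interp(coarse.t, fine.t, fine.mu_s)
        assert np.max(np.abs(coarse.mu_s - interp)) < 1e-6

    def test_agrees_with_adaptive_reference(self, preset):
        """Independent oracle: scipy's adaptive RK45 at tight tolerance."""
        p = preset.params

        def rhs(t, y):
            mu = min(y[0], 1.0)
            sw = 0.5 * (math.tanh(p.alpha * (t - p.t_ind)) + 1.0)
            return [p.b0 * (1 - mu) / (p.psi * math.exp(-p.k_deg * t) + 1 - mu) * sw]

        sol = solve_ivp(rhs, (0, 30.0), [0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        mine = integrate_rk4(p, 30.0, 0.1)
        ref = np.minimum(sol.sol(mine.t)[0], 1.0)
        assert np.max(np.abs(mine.mu_s - ref)) < 1e-6

    def test_heaviside_limit(self, plga15):
        """alpha -> inf recovers the sharp induction-switch dynamics."""
        p = plga15.params
        sharp = integrate_rk4(p, 42.0, 0.001, switch="heaviside")
        smooth = integrate_rk4(p.replace(alpha=1e4), 42.0, 0.001)
        assert np.max(np.abs(sharp.mu_s - smooth.mu_s)) < 1e-4

    def test_pre_induction_quiescence(self, preset):
        p = preset.params
        c = integrate_rk4(p, 42.0, 0.05)
        assert c.interp_mu_s([p.t_ind / 2])[0] < 1e-3

    @pytest.mark.parametrize("t_end,dt", [(0.0, 0.1), (10.0, -1.0), (1.0, 2.0)])
    def test_bad_grid_arguments(self, plga15, t_end, dt):
        with pytest.raises(ValueError):
            integrate_rk4(plga15.params, t_end, dt)


class TestDeriveB0Psi:
    PHYS = dict(v_ms=7e-9, mw_s=500.0, mw_p0=4.0e4, m_ms0=9e-9, k_m=2e-3,
                r0=1e-2)

    def test_explicit_products(self):
        phys = PhysicalParams(**self.PHYS)
        b0, psi = derive_b0_psi(phys)
        assert b0 == pytest.approx(7e-9 * 500.0 * 1e-2 / 9e-9)
        assert psi == pytest.approx(2e-3 * 7e-9 * 4.0e4 / 9e-9)

    def test_doubling_mass_halves_both(self):
        b0, psi = derive_b0_psi(PhysicalParams(**self.PHYS))
        heavier = {**self.PHYS, "m_ms0": 2 * self.PHYS["m_ms0"]}
        b0h, psih = derive_b0_psi(PhysicalParams(**heavier))
        assert b0h == pytest.approx(b0 / 2)
        assert psih == pytest.approx(psi / 2)

    def test_km_from_elementary_constants(self):
        phys = PhysicalParams(
            v_ms=7e-9, mw_s=500.0, mw_p0=4.0e4, m_ms0=9e-9,
            k1=10.0, k_m1=1.5e-2, k2=5e-3, a0=2.0,
        )
        assert phys.k_m == pytest.approx((1.5e-2 + 5e-3) / 10.0)
        assert phys.r0 == pytest.approx(5e-3 * 2.0)

    def test_simulation_identical_to_precomputed_lumped_params(self, plga15):
        """Deriving (B0, psi) then simulating must equal simulating with the
        lumped values directly (bitwise)."""
        target = plga15.params
        phys = PhysicalParams(
            v_ms=1.0, mw_s=1.0, mw_p0=1.0, m_ms0=1.0,
            k_m=target.psi, r0=target.b0,
        )
        b0, psi = derive_b0_psi(phys)
        p_derived = ModelParams(b0=b0, psi=psi, t_ind=target.t_ind,
                                k_deg=target.k_deg)
        t = np.linspace(0, 42, 15)
        assert np.array_equal(simulate_front(p_derived, t),
                              simulate_front(target, t))

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            PhysicalParams(**{**self.PHYS, "m_ms0": 0.0})
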