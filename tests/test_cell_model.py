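"""Unit and property tests for the myocyte contraction model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvelastance.cell_model import (CellState, active_force, ca_pump,
                                    ca_release, cell_derivatives, cell_step,
                                    detachment_rates, force_length_slopes,
                                    passive_force, steady_state_hp)
from lvelastance.params import CaParams, CellParams, PassiveParams

P = CellParams()
CA = CaParams()
PP = PassiveParams()


class TestDetachmentRates:
    def test_resting_extensions_give_baseline_rates(self):
        g, g_d, _ = detachment_rates(L=1.2, h_w=P.h_wr, dXw_dt=-1e-6, p=P)
        assert g == pytest.approx(0.0023)
        assert g_d == pytest.approx(0.0333)

    def test_large_extension_saturates_g(self):
        g, _, _ = detachment_rates(L=1.2, h_w=1e3, dXw_dt=-1e-6, p=P)
        assert g == pytest.approx(P.Z_a + P.Y_v)  # 1.5023

    def test_length_term_adds_quadratically(self):
        _, g_d, _ = detachment_rates(L=1.3, h_w=P.h_wr, dXw_dt=-1e-6, p=P)
        assert g_d == pytest.approx(0.0333 + 1.0 * 0.1 ** 2)

    def test_lengthening_attenuates_sensitivity(self):
        _, _, gm_short = detachment_rates(1.1, 0.001, -1.0, P)
        _, _, gm_long = detachment_rates(1.1, 0.001, +1.0, P)
        assert gm_short == pytest.approx(P.gamma)
        assert gm_long == pytest.approx(P.gamma / P.K_gamma)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            detachment_rates(float("nan"), 0.0, 0.0, P)


class TestForces:
    def test_no_occupancy_no_force(self):
        s = CellState(X_p=1.0, X_w=1.0)
        assert active_force(s, 1.1, P) == 0.0

    def test_single_power_state_value(self):
        s = CellState(TSCa3p=1.0, X_p=1.2 - P.h_pr, X_w=1.2)
        assert active_force(s, 1.2, P) == pytest.approx(2700 * 1.0 * 0.006)  # 16.2

    def test_force_linear_in_occupancy(self):
        s1 = CellState(TSCa3=.1, TSCa3w=.2, TSCa3p=.3, TSp=.1, TSw=.05,
                       X_p=1.0, X_w=1.05)
        s2 = CellState(TSCa3=.2, TSCa3w=.4, TSCa3p=.6, TSp=.2, TSw=.1,
                       X_p=1.0, X_w=1.05)
        assert active_force(s2, 1.1, P) == pytest.approx(2 * active_force(s1, 1.1, P))

    def test_passive_force_zero_at_slack(self):
        assert passive_force(PP.L_0, PP) == 0.0

    def test_passive_force_compressive_branch(self):
        assert passive_force(1.0, PP) == pytest.approx(-7.561 * (1 - 1.0 / 1.043))

    def test_passive_force_extension_branch(self):
        expect = 0.2692 * (math.exp(28.08 * (1.1 / 1.043 - 1)) - 1)
        assert passive_force(1.1, PP) == pytest.approx(expect)

    def test_passive_force_continuous_and_monotone(self):
        L = np.linspace(0.9, 1.2, 2001)
        F = passive_force(L, PP)
        assert np.all(np.diff(F) > 0)
        eps = 1e-9
        assert passive_force(PP.L_0 - eps, PP) == pytest.approx(
            passive_force(PP.L_0 + eps, PP), abs=1e-6)


class TestCalcium:
    def test_release_at_cycle_start_is_resting_leak(self):
        assert ca_release(0.0, CA) == pytest.approx(0.03)

    def test_release_peak_at_t1(self):
        assert ca_release(CA.t_1, CA) == pytest.approx(3.23)
        t = np.linspace(0.0, 100.0, 10001)
        assert t[np.argmax(ca_release(t, CA))] == pytest.approx(CA.t_1, abs=0.02)

    def test_pump_half_max_at_km(self):
        assert ca_pump(0.2, CA) == pytest.approx(CA.K_p / 2)

    def test_pump_resting_fixed_point(self):
        # uptake at 0.1 uM equals the resting leak, defining resting Ca
        assert ca_pump(0.1, CA) == pytest.approx(CA.Q_pump_rest)
        assert CA.ca_rest == pytest.approx(0.1)

    def test_pump_limits(self):
        assert ca_pump(1e9, CA) == pytest.approx(CA.K_p)
        assert ca_pump(0.0, CA) == 0.0


pools = st.floats(0.0, 4.0)


class TestDerivatives:
    def test_resting_extensions_freeze_sliding(self):
        s = CellState(X_p=1.1 - P.h_pr, X_w=1.1 - P.h_wr)
        d = cell_derivatives(s, 1.1, 0.0, 500.0, P, CA)
        assert d.X_p == pytest.approx(0.0, abs=1e-15)
        assert d.X_w == pytest.approx(0.0, abs=1e-15)

    @given(tsca3=pools, tsca3w=pools, tsca3p=pools, tsp=pools, tsw=pools,
           ca=st.floats(0.01, 2.0), L=st.floats(0.9, 1.2))
    def test_total_troponin_conserved(self, tsca3, tsca3w, tsca3p, tsp, tsw, ca, L):
        """The six troponin-system pools exchange mass but never create it:
        the tracked-pool derivatives sum to minus the free-pool derivative."""
        s = CellState(tsca3, tsca3w, tsca3p, tsp, tsw, X_p=L - 0.005,
                      X_w=L - 0.0001, Ca=ca)
        d = cell_derivatives(s, L, 0.0, 500.0, P, CA)
        tracked = d.TSCa3 + d.TSCa3w + d.TSCa3p + d.TSp + d.TSw
        # independent free-troponin balance: binding out, unbinding + g_d in
        ts_free = P.TS_tot - s.bound_total()
        h_w = L - s.X_w
        _, g_d, _ = detachment_rates(L, h_w, P.B * (h_w - P.h_wr), P)
        d_free = P.Z_b * s.TSCa3 - P.Y_b * ts_free * ca ** 3 + g_d * s.TSw
        assert tracked + d_free == pytest.approx(0.0, abs=1e-12 * P.TS_tot)

    def test_negative_free_troponin_raises(self):
        s = CellState(TSCa3=P.TS_tot, TSw=1.0, X_p=1.0, X_w=1.0)
        with pytest.raises(ValueError, match="free troponin"):
            cell_derivatives(s, 1.1, 0.0, 500.0, P, CA)

    def test_relaxes_to_resting_calcium_and_zero_force(self):
        """With the release pulse long over, the cell settles at the pump
        fixed point (0.1 uM) with negligible active force."""
        s = CellState(TSCa3=2.0, TSCa3w=0.2, TSCa3p=0.2, TSp=0.1, TSw=0.1,
                      X_p=1.09, X_w=1.095, Ca=0.8)
        L, dt = 1.097, 0.01
        for i in range(60_000):
            s = cell_step(s, L, 0.0, 1e6, dt, P, CA)
        assert s.Ca == pytest.approx(0.1, rel=2e-2)
        rest = active_force(CellState.resting(L, P, CA), L, P)
        assert active_force(s, L, P) == pytest.approx(rest, abs=0.1)


class TestCellStep:
    def test_euler_definition(self):
        s = CellState(TSCa3=1.0, TSCa3w=0.1, X_p=1.0, X_w=1.0, Ca=0.5)
        d = cell_derivatives(s, 1.1, 0.0, 4.0, P, CA)
        out = cell_step(s, 1.1, 0.0, 4.0, 0.01, P, CA)
        np.testing.assert_allclose(out.to_array(), s.to_array() + 0.01 * d.to_array(),
                                   rtol=0, atol=1e-15)

    def test_undershoot_clips_and_warns(self):
        s = CellState(TSw=1e-9, X_p=1.0, X_w=1.0, Ca=0.1)
        with pytest.warns(UserWarning, match="undershoot"):
            out = cell_step(s, 1.1, 0.0, 500.0, 50.0, P, CA)
        assert out.TSw == 0.0

    def test_first_order_convergence(self):
        """Halving dt halves the trajectory error (forward Euler)."""
        def run(dt, n):
            s = CellState(TSCa3=1.0, X_p=1.09, X_w=1.095, Ca=0.6)
            for i in range(n):
                s = cell_step(s, 1.097, 0.0, i * dt, dt, P, CA)
            return s.to_array()

        ref = run(0.0025, 4000)
        err1 = np.abs(run(0.02, 500) - ref).max()
        err2 = np.abs(run(0.01, 1000) - ref).max()
        assert err1 / err2 == pytest.approx(2.0, rel=0.35)


class TestSteadyStateExtension:
    def test_values_and_slope(self):
        assert steady_state_hp(0.0, P) == pytest.approx(P.h_pr)
        assert steady_state_hp(-1e-4, P) == pytest.approx(0.0058)
        slope = (steady_state_hp(1e-3, P) - steady_state_hp(0.0, P)) / 1e-3
        assert slope == pytest.approx(1 / P.B)  # 2 ms

    def test_hp_relaxes_at_rate_B(self):
        """Under constant L and Ca, h_p decays to h_pr exponentially with
        rate B (the sliding crossbridge re-equilibrating)."""
        L, dt = 1.1, 0.01
        s = CellState(X_p=L - 0.01, X_w=L - P.h_wr, Ca=0.1)
        gaps = []
        for i in range(600):
            gaps.append((L - s.X_p) - P.h_pr)
            s = cell_step(s, L, 0.0, 1e6, dt, P, CA)
        gaps = np.asarray(gaps)
        rate = -np.diff(np.log(gaps))[::50] / dt
        # the Euler recursion gap -> gap*(1 - B*dt) decays at exactly
        # -ln(1 - B*dt)/dt, which is B + O(dt)
        discrete = -math.log1p(-P.B * dt) / dt
        np.testing.assert_allclose(rate, discrete, rtol=1e-9)
        np.testing.assert_allclose(rate, P.B, rtol=5e-3)


class TestForceLengthSlopes:
    def test_zero_occupancy(self):
        s = CellState(X_p=1.0, X_w=1.0)
        dFb, _ = force_length_slopes(s, 1.1, P, PP)
        assert dFb == 0.0

    def test_passive_slope_at_slack(self):
        _, dFp = force_length_slopes(CellState(), PP.L_0, P, PP)
        assert dFp == pytest.approx(PP.K_PE * PP.D / PP.L_0)
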