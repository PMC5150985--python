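"""Piecewise dimple ODE: oracle equivalence, events, modes and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striderjump import (
    FluidProperties,
    JumpMode,
    JumpParameters,
    NoTakeoffError,
    SolverOptions,
    linear_pushing_oracle,
    resonant_maximum,
    simulate_jump,
    takeoff_velocity_physical,
)
from striderjump.dynamics import Stage, dimple_ode_rhs


def params_from_k(k: float, L: float, M: float = 0.5, **kw) -> JumpParameters:
    """JumpParameters with a prescribed spring constant k = 2/(M Omega^2)."""
    return JumpParameters(Omega=math.sqrt(2.0 / (M * k)), mass_index=M, reach=L, **kw)


class TestRhs:
    def test_initial_acceleration_is_drive_only(self):
        p = JumpParameters(Omega=1.0, mass_index=0.5, reach=2.5)
        _, acc = dimple_ode_rhs(0.0, (0.0, 0.0), p, Stage.PUSHING)
        assert acc == pytest.approx(2.0 * p.reach)

    def test_closing_rhs_continuous_at_stage_switch(self):
        p = JumpParameters(Omega=1.0, mass_index=0.5, reach=2.5)
        tau_m, H_m = 1.0, 0.8
        push = dimple_ode_rhs(tau_m, (H_m, 0.0), p, Stage.PUSHING)
        close = dimple_ode_rhs(tau_m, (H_m, 0.0), p, Stage.CLOSING, (tau_m, H_m))
        assert push[1] == pytest.approx(close[1], rel=1e-14)

    def test_pushing_is_driven_linear_oscillator(self):
        p = JumpParameters(Omega=1.3, mass_index=0.8, reach=1.7)
        k = p.stiffness
        for tau, H in [(0.2, 0.1), (0.7, 0.9), (1.2, 1.3)]:
            _, acc = dimple_ode_rhs(tau, (H, 0.0), p, Stage.PUSHING)
            assert acc == pytest.approx(2 * p.reach * math.cos(2 * tau) - k * H, rel=1e-14)

    def test_degenerate_closing_context_rejected(self):
        p = JumpParameters(Omega=1.0, mass_index=0.5, reach=1.0)
        with pytest.raises(Exception):
            dimple_ode_rhs(1.0, (0.5, 0.0), p, Stage.CLOSING, (0.9, 0.0))


class TestPushingOracle:
    @pytest.mark.parametrize("k", [0.5, 2.0, 4.0, 8.0, 40.0])
    @pytest.mark.parametrize("L", [0.5, 2.0, 5.0])
    def test_numeric_matches_closed_form(self, k, L):
        p = params_from_k(k, L, initial_depth=1e-8)
        res = simulate_jump(p)
        push = res.stage == "pushing"
        err = np.abs(res.H[push] - linear_pushing_oracle(p, res.tau[push]))
        assert err.max() < 1e-6

    def test_resonant_case_maximum(self):
        # k = 4: H = (L/2) tau sin 2tau, first max solves tan x = -x
        p = params_from_k(4.0, 1.0)
        res = simulate_jump(p)
        tau_m, hm_per_L = resonant_maximum()
        assert tau_m == pytest.approx(1.0144, abs=1e-4)
        assert res.tau_m == pytest.approx(tau_m, abs=1e-4)
        assert res.H_m == pytest.approx(hm_per_L * p.reach, abs=1e-4)

    def test_resonant_form_value(self):
        p = params_from_k(4.0, 1.0)
        tau = math.pi / 4
        assert linear_pushing_oracle(p, tau) == pytest.approx(0.5 * 1.0 * tau, rel=1e-12)

    def test_oracle_initial_condition(self):
        for k in (0.5, 4.0, 9.0):
            assert linear_pushing_oracle(params_from_k(k, 2.0), 0.0) == 0.0


class TestModes:
    def test_weak_spring_long_reach_breaks_meniscus(self):
        # k << 4 so H ~ L(1-cos 2tau)/2 exceeds sqrt(2) for L = 5
        res = simulate_jump(params_from_k(0.05, 5.0))
        assert res.mode is JumpMode.MENISCUS_BREAKING
        assert res.tau_b is not None and res.V_t is not None
        assert res.H.max() <= res.params.breaking_depth + 1e-6

    def test_quasi_static_stroke_transfers_no_momentum(self):
        # V_t vanishes linearly with Omega: slow strokes transfer no momentum
        slow = simulate_jump(JumpParameters(Omega=0.02, mass_index=0.5, reach=2.0))
        slower = simulate_jump(JumpParameters(Omega=0.01, mass_index=0.5, reach=2.0))
        assert slow.mode is not JumpMode.MENISCUS_BREAKING
        assert slow.V_t < 0.05
        assert slower.V_t < slow.V_t

    def test_post_takeoff_closing_leaves_before_stroke_end(self):
        res = simulate_jump(JumpParameters(Omega=0.7, mass_index=0.5, reach=4.0))
        assert res.mode is JumpMode.POST_TAKEOFF_CLOSING
        assert res.tau_t < math.pi / 2
        assert res.V_t > 0

    def test_pre_takeoff_closing_keeps_dimple_past_stroke_end(self):
        res = simulate_jump(JumpParameters(Omega=1.0, mass_index=0.5, reach=1.0))
        assert res.mode is JumpMode.PRE_TAKEOFF_CLOSING
        assert res.tau_c == pytest.approx(math.pi / 2)
        assert res.tau_t > math.pi / 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        Omega=st.floats(0.1, 4.0),
        M=st.floats(0.05, 4.0),
        L=st.floats(0.3, 7.0),
    )
    def test_mode_trichotomy(self, Omega, M, L):
        res = simulate_jump(JumpParameters(Omega=Omega, mass_index=M, reach=L))
        assert res.mode in JumpMode
        assert np.all(res.H >= -1e-9)


class TestInvariants:
    @pytest.mark.parametrize("Omega,M,L", [
        (0.9, 0.5, 3.0), (1.5, 0.2, 2.0), (0.5, 2.0, 4.0),
    ])
    def test_momentum_consistency_along_solution(self, Omega, M, L):
        # v = int F dt / m: kinematic V equals the accumulated impulse
        res = simulate_jump(JumpParameters(Omega=Omega, mass_index=M, reach=L))
        stroke = res.stage != "post_closing"
        err = np.abs(res.V[stroke] - Omega * res.impulse[stroke])
        assert err.max() < 1e-6

    def test_dimple_rate_sign_splits_stages(self):
        # legs outrun the body before tau_m (H' > 0), lag after (H' < 0)
        res = simulate_jump(JumpParameters(Omega=0.7, mass_index=0.5, reach=4.0))
        before = (res.tau > 1e-6) & (res.tau < res.tau_m - 1e-3)
        after = (res.tau > res.tau_m + 1e-3) & (res.tau < res.tau_t - 1e-3)
        assert np.all(res.Hprime[before] > 0)
        assert np.all(res.Hprime[after] < 0)

    def test_stationary_points_at_start_and_maximum(self):
        res = simulate_jump(JumpParameters(Omega=1.0, mass_index=0.5, reach=2.0))
        assert res.Hprime[0] == pytest.approx(0.0, abs=1e-12)
        i_m = np.argmin(np.abs(res.tau - res.tau_m))
        assert abs(res.Hprime[i_m]) < 1e-4

    def test_epsilon_insensitivity(self):
        vts = [
            simulate_jump(JumpParameters(Omega=0.9, mass_index=0.5, reach=3.0,
                                         initial_depth=eps)).V_t
            for eps in (1e-8, 1e-6, 1e-4)
        ]
        assert max(vts) - min(vts) < 1e-3 * max(vts)

    def test_tolerance_halving_convergence(self):
        p = JumpParameters(Omega=0.9, mass_index=0.5, reach=3.0)
        v1 = simulate_jump(p, SolverOptions(rtol=1e-8)).V_t
        v2 = simulate_jump(p, SolverOptions(rtol=5e-9)).V_t
        assert abs(v1 - v2) < 1e-6


class TestPhysicalConversion:
    def test_takeoff_velocity_scale(self, water):
        res = simulate_jump(JumpParameters(Omega=0.7, mass_index=0.5, reach=4.0))
        v = takeoff_velocity_physical(res, water)
        assert v == pytest.approx(res.V_t * 0.1631, rel=1e-3)

    def test_scale_doubles_with_g_and_lc(self, water):
        res = simulate_jump(JumpParameters(Omega=0.7, mass_index=0.5, reach=4.0))
        # doubling g and l_c quadruples g*l_c: v_t scales by 2.  l_c doubles
        # when sigma x8 and g x2 (l_c = sqrt(sigma/(rho g))).
        scaled = FluidProperties(water.density, 8 * water.surface_tension,
                                 water.viscosity, 2 * water.gravity)
        assert scaled.capillary_length == pytest.approx(2 * water.capillary_length)
        assert takeoff_velocity_physical(res, scaled) == pytest.approx(
            2 * takeoff_velocity_physical(res, water)
        )

    def test_no_takeoff_signals(self):
        res = simulate_jump(JumpParameters(Omega=0.02, mass_index=4.0, reach=0.5,
                                           include_weight=True))
        if res.mode is JumpMode.NO_TAKEOFF:
            with pytest.raises(NoTakeoffError):
                takeoff_velocity_physical(res, FluidProperties())

    def test_escape_time_conversion(self):
        res = simulate_jump(JumpParameters(Omega=0.7, mass_index=0.5, reach=4.0))
        assert res.escape_time(omega=50.0) == pytest.approx(res.tau_t / 50.0)
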