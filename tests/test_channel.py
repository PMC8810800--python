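"""BacNav gating kinetics: fitted curves, asymptotes, gate updates and
the macroscopic current law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacnavsim.channel import (
    BacNavParams,
    ChannelGates,
    bacnav_current,
    h_inf,
    m_inf,
    step_gates,
    tau_h,
    tau_m,
)
from bacnavsim.errors import InvalidInputError
from bacnavsim.models._kernels import bac_hinf, bac_minf, bac_tauh, bac_taum


# scalar reference values evaluated with 40-digit arithmetic
@pytest.mark.parametrize("func,vm,expected,tol", [
    (tau_m, 200.0, 1.6600015, 1e-6),        # depolarized asymptote 1.66
    (tau_m, -160.0, 1.66, 1e-9),            # overflow-guarded asymptote
    (tau_m, -10.0, 5.028669237439639, 1e-9),
    (tau_h, 100.0, 9.593, 1e-12),           # depolarized asymptote
    (tau_h, -80.0, 22.045002701233329, 1e-9),
    (tau_h, -27.15, 61.867292375036191, 1e-9),
    (m_inf, -22.5, 0.5, 1e-12),             # half-activation midpoint
    (m_inf, 100.0, 1.0, 1e-12),
    (m_inf, -33.3, 0.018091021649723661, 1e-12),
    (h_inf, -77.05, 0.5, 1e-12),            # half-inactivation midpoint
    (h_inf, -160.0, 0.99958881359352196, 1e-12),
    (h_inf, -30.0, 0.011867743277017730, 1e-12),
])
def test_gating_curve_values(func, vm, expected, tol):
    assert func(vm) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("func", [tau_m, tau_h, m_inf, h_inf])
def test_nonfinite_vm_rejected(func):
    with pytest.raises(InvalidInputError):
        func(np.nan)
    with pytest.raises(InvalidInputError):
        func(np.inf)


def test_time_constants_finite_positive_over_extreme_range():
    vm = np.linspace(-500.0, 500.0, 2001)
    tm, th = tau_m(vm), tau_h(vm)
    assert np.all(np.isfinite(tm)) and np.all(tm > 1.66 - 1e-9)
    assert np.all(np.isfinite(th)) and np.all(th > 9.593 - 1e-9)


def test_steady_states_monotone_and_bounded():
    vm = np.linspace(-120.0, 40.0, 3201)
    m, h = m_inf(vm), h_inf(vm)
    assert np.all(np.diff(m) > 0) and np.all(np.diff(h) < 0)
    wide = np.linspace(-500.0, 500.0, 2001)
    mw, hw = m_inf(wide), h_inf(wide)
    assert np.all(np.diff(mw) >= 0) and np.all(np.diff(hw) <= 0)
    assert 0.0 <= mw.min() and mw.max() <= 1.0
    assert 0.0 <= hw.min() and hw.max() <= 1.0


def test_kernel_scalars_match_reference_functions():
    """The compiled scalar twins used inside the ionic kernels must agree
    with the reference vector implementation."""
    for vm in np.linspace(-150.0, 100.0, 101):
        assert bac_minf(vm) == pytest.approx(float(m_inf(vm)), rel=1e-14)
        assert bac_hinf(vm) == pytest.approx(float(h_inf(vm)), rel=1e-14)
        assert bac_taum(vm) == pytest.approx(float(tau_m(vm)), rel=1e-14)
        assert bac_tauh(vm) == pytest.approx(float(tau_h(vm)), rel=1e-14)


class TestStepGates:
    def test_zero_dt_is_identity(self):
        g = ChannelGates(0.3, 0.7)
        g2 = step_gates(g, -40.0, 0.0)
        assert (g2.m, g2.h) == (0.3, 0.7)

    def test_huge_dt_fully_relaxes(self):
        g = step_gates(ChannelGates(0.0, 1.0), -30.0, 1e6)
        assert g.m == pytest.approx(float(m_inf(-30.0)), abs=1e-12)
        assert g.h == pytest.approx(float(h_inf(-30.0)), abs=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            step_gates(ChannelGates(0.5, 0.5), -40.0, -1.0)

    def test_matches_fine_step_euler_oracle(self):
        """Exact-relaxation at dt=0.01 ms vs brute-force explicit Euler at
        dt=1e-4 ms over 10 ms at fixed voltage."""
        vm = -20.0
        g_rl = ChannelGates.at_rest(-80.0)
        m_e, h_e = g_rl.m, g_rl.h
        fine = 2e-5
        minf, hinf = float(m_inf(vm)), float(h_inf(vm))
        tm, th = float(tau_m(vm)), float(tau_h(vm))
        for _ in range(int(10.0 / fine)):
            m_e += fine * (minf - m_e) / tm
            h_e += fine * (hinf - h_e) / th
        for _ in range(1000):
            g_rl = step_gates(g_rl, vm, 0.01)
        assert abs(g_rl.m - m_e) < 1e-6
        assert abs(g_rl.h - h_e) < 1e-6

    def test_relaxation_rate_matches_one_over_tau(self):
        """log-linear decay of (g - g_inf) proceeds at rate 1/tau within
        0.1% at fixed voltage."""
        vm = -50.0
        g = ChannelGates.at_rest(-120.0)
        hinf, th = float(h_inf(vm)), float(tau_h(vm))
        d0 = g.h - hinf
        g1 = step_gates(g, vm, 5.0)
        rate = -np.log((g1.h - hinf) / d0) / 5.0
        assert rate == pytest.approx(1.0 / th, rel=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(m0=st.floats(0, 1), h0=st.floats(0, 1),
           vms=st.lists(st.floats(-150, 80), min_size=1, max_size=20),
           dts=st.lists(st.floats(0, 50), min_size=1, max_size=20))
    def test_gates_stay_bounded_for_any_schedule(self, m0, h0, vms, dts):
        g = ChannelGates(m0, h0)
        for vm, dt in zip(vms, dts):
            g = step_gates(g, vm, dt)
            assert 0.0 <= g.m <= 1.0 and 0.0 <= g.h <= 1.0


class TestBacnavCurrent:
    def test_closed_gate_zero(self):
        p = BacNavParams(gbar_1x=5.0, x_level=1.0, e_rev=70.0)
        assert bacnav_current(-120.0, ChannelGates(0.0, 1.0), p) == 0.0

    def test_zero_driving_force(self):
        p = BacNavParams(gbar_1x=5.0, x_level=1.0, e_rev=50.0)
        assert bacnav_current(50.0, ChannelGates(0.5, 0.5), p) == 0.0

    def test_current_law_arithmetic(self):
        # I = X g m h^2 (V - E): 2 * 1 * 0.5 * 0.25 * (0 - 50) = -12.5
        p = BacNavParams(gbar_1x=1.0, x_level=2.0, e_rev=50.0)
        assert bacnav_current(0.0, ChannelGates(0.5, 0.5), p) == \
            pytest.approx(-12.5)

    def test_linear_in_expression_level(self):
        g = ChannelGates(0.4, 0.6)
        i1 = bacnav_current(-10.0, g, BacNavParams(3.0, 1.0, 60.0))
        i2 = bacnav_current(-10.0, g, BacNavParams(3.0, 2.0, 60.0))
        assert i2 == pytest.approx(2.0 * i1, rel=1e-15)

    def test_zero_expression_removes_channel(self):
        p = BacNavParams(gbar_1x=9.0, x_level=0.0, e_rev=70.0)
        assert bacnav_current(0.0, ChannelGates(1.0, 1.0), p) == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            BacNavParams(gbar_1x=0.0)
        with pytest.raises(InvalidInputError):
            BacNavParams(gbar_1x=1.0, x_level=-0.1)
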