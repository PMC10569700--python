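"""Gating mathematics: Boltzmann steady states, time constants,
conductance laws and density mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucpatch.gates import (
    ChannelMix,
    GateSpec,
    gate_derivative,
    k_conductance,
    mixed_densities,
    na_conductance,
    steady_state,
    time_constant,
)
from nucpatch.presets import species_preset

V_GRID = np.linspace(-120.0, 60.0, 181)


def act_gate(vhalf=-32.1, q=5.0):
    return GateSpec(vhalf, q, "activation", (0.2, 0.2, -38.0, 10.0))


def inact_gate(vhalf=-66.0, q=7.0):
    return GateSpec(vhalf, q, "inactivation", (0.02, 0.01, -45.0, -60.0, 6.0, 7.0))


class TestSteadyState:
    def test_boltzmann_midpoint_is_half(self):
        for gate in (act_gate(), inact_gate(), act_gate(q=12.0)):
            assert steady_state(gate.vhalf, gate) == pytest.approx(0.5)

    def test_human_na_activation_midpoint(self):
        """The shipped human Na+ activation gate is half-open at -32.1 mV."""
        gate = species_preset("human_na").m
        assert gate.vhalf == -32.1
        assert steady_state(-32.1, gate) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert steady_state(1e3, act_gate()) == pytest.approx(1.0)
        assert steady_state(-1e3, act_gate()) == pytest.approx(0.0, abs=1e-12)
        assert steady_state(1e3, inact_gate()) == pytest.approx(0.0, abs=1e-12)
        assert steady_state(-1e3, inact_gate()) == pytest.approx(1.0)

    def test_monotone_and_bounded_for_all_preset_gates(self):
        for name in ("human_na", "mouse_na", "human_k", "mouse_k"):
            ch = species_preset(name)
            gates = (
                (ch.m, ch.h) if hasattr(ch, "h") else (ch.m, ch.h1, ch.h2)
            )
            for g in gates:
                y = steady_state(V_GRID, g)
                assert np.all((y >= 0) & (y <= 1))
                dy = np.diff(y)
                assert np.all(dy > 0) if g.kind == "activation" else np.all(dy < 0)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            steady_state(np.nan, act_gate())


class TestTimeConstant:
    def test_equal_unit_rates_give_half_ms(self):
        # at V = tha the linoid evaluates to qa, so ra = rb = 1/qa makes
        # alpha = beta = 1 ms^-1 and tau = 1/(alpha+beta) = 0.5 ms
        gate = GateSpec(-30.0, 6.0, "activation", (0.1, 0.1, -40.0, 10.0))
        assert time_constant(-40.0, gate) == pytest.approx(1.0 / (2 * 0.1 * 10.0))
        unit = GateSpec(-30.0, 6.0, "activation", (1 / 8.0, 1 / 8.0, -40.0, 8.0))
        assert time_constant(-40.0, unit) == pytest.approx(0.5)

    def test_positive_everywhere_for_presets(self):
        for name in ("human_na", "mouse_na", "human_k", "mouse_k"):
            ch = species_preset(name)
            gates = [ch.m, ch.h] if hasattr(ch, "h") else [ch.m, ch.h1, ch.h2]
            for g in gates:
                tau = time_constant(V_GRID, g)
                assert np.all(tau > 0)
                assert np.all(np.isfinite(tau))

    def test_matches_direct_rate_evaluation(self):
        """tau from the API equals 1/(alpha+beta) evaluated symbolically."""
        gate = species_preset("human_na").h
        rd, rg, thi1, thi2, qd, qg = gate.kin

        def linoid(x, q):
            return q if abs(x) < 1e-12 else x / (1.0 - np.exp(-x / q))

        for v in (-100.0, -66.0, -40.0, 0.0, 40.0):
            alpha = rd * linoid(v - thi1, qd)
            beta = rg * linoid(thi2 - v, qg)
            assert time_constant(v, gate) == pytest.approx(1.0 / (alpha + beta))

    def test_two_regime_selects_by_gate_value(self):
        g = GateSpec(-55.0, 6.0, "inactivation", (200.0, 80.0), tau_form="two_regime")
        hinf = steady_state(-70.0, g)
        assert time_constant(-70.0, g, x=hinf + 0.1) == 200.0
        assert time_constant(-70.0, g, x=hinf - 0.1) == 80.0

    def test_parameter_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(-30.0, 5.0, "activation", (0.1, 0.2, 0.3))

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(-30.0, 0.0, "activation", (0.1, 0.1, -40.0, 10.0))


class TestGateDerivative:
    def test_fixed_point_and_sign(self):
        gate = act_gate()
        for v in (-80.0, -32.1, 0.0):
            xinf = steady_state(v, gate)
            assert gate_derivative(xinf, v, gate) == pytest.approx(0.0, abs=1e-12)
            assert gate_derivative(min(xinf + 0.2, 1.0), v, gate) < 0
            assert gate_derivative(max(xinf - 0.2, 0.0), v, gate) > 0

    def test_analytic_relaxation_matches_euler_at_small_dt(self):
        """Forward-integrating dx/dt at fixed V converges to the closed form
        x(t) = xinf - (xinf - x0) exp(-t/tau) as dt -> 0."""
        gate = inact_gate()
        v, x0, t_end = -50.0, 0.9, 5.0
        xinf = steady_state(v, gate)
        tau = time_constant(v, gate)
        exact = xinf - (xinf - x0) * np.exp(-t_end / tau)
        errs = []
        for dt in (1e-3, 5e-4):
            x = x0
            for _ in range(int(t_end / dt)):
                x += dt * gate_derivative(x, v, gate)
            errs.append(abs(x - exact))
        assert errs[0] < 1e-3 * abs(exact)
        assert errs[1] < 0.6 * errs[0]  # first-order convergence

    def test_out_of_range_gate_rejected(self):
        with pytest.raises(ValueError):
            gate_derivative(1.2, -50.0, act_gate())


class TestConductances:
    def test_na_conductance_limits(self):
        ch = species_preset("human_na").with_gmax(80.0)
        assert na_conductance(1.0, 1.0, ch) == pytest.approx(80.0)
        assert na_conductance(0.7, 0.0, ch) == 0.0
        assert na_conductance(0.5, 0.5, ch) == pytest.approx(80.0 / 16.0)

    def test_k_conductance_three_fraction_arithmetic(self):
        ch = species_preset("human_k").with_gmax(100.0)
        assert ch.frac_inact == 0.85 and ch.frac_h2 == 0.4
        assert k_conductance(1.0, 1.0, 1.0, ch) == pytest.approx(100.0)
        # only the non-inactivating 15% survives full inactivation
        assert k_conductance(1.0, 0.0, 0.0, ch) == pytest.approx(15.0)
        # fast fraction open, slow fraction inactivated:
        # 0.85*(0.6*1 + 0.4*0) + 0.15 = 0.66
        assert k_conductance(1.0, 1.0, 0.0, ch) == pytest.approx(66.0)

    def test_noninactivating_floor(self):
        ch = species_preset("mouse_k").with_gmax(50.0)
        for m in (0.2, 0.6, 1.0):
            g = k_conductance(m, 0.0, 0.0, ch)
            assert g >= 0.15 * 50.0 * m**2 - 1e-12

    def test_gate_range_checked(self):
        ch = species_preset("human_k")
        with pytest.raises(ValueError):
            k_conductance(1.5, 1.0, 1.0, ch)


class TestChannelMix:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        hf_na=st.floats(0.0, 1.0),
        hf_k=st.floats(0.0, 1.0),
        g_na=st.floats(0.0, 1e3),
        g_k=st.floats(0.0, 1e3),
    )
    def test_density_conservation(self, hf_na, hf_k, g_na, g_k):
        d = mixed_densities(ChannelMix(g_na, g_k, hf_na, hf_k))
        assert sum(d.values()) == pytest.approx(g_na + g_k, rel=1e-12, abs=1e-9)
        assert all(v >= 0 for v in d.values())

    def test_pure_fractions(self):
        d = mixed_densities(ChannelMix(100.0, 40.0, 1.0, 0.0))
        assert d["na_human"] == 100.0 and d["na_mouse"] == 0.0
        assert d["k_human"] == 0.0 and d["k_mouse"] == 40.0
        d = mixed_densities(ChannelMix(100.0, 40.0, 0.5, 0.5))
        assert d["na_human"] == d["na_mouse"] == 50.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ChannelMix(100.0, 40.0, 1.5, 0.5)
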