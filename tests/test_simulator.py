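"""Single-compartment integrator and voltage-clamp protocol battery."""

import numpy as np
import pytest

from nucpatch.gates import GateSpec, NaChannelModel, steady_state, time_constant
from nucpatch.presets import species_preset
from nucpatch.simulator import (
    PatchModel,
    ProtocolSpec,
    ap_clamp,
    find_rheobase,
    integrate,
    recovery_protocol,
    simulate_ap_train,
    steady_state_activation_protocol,
    steady_state_inactivation_protocol,
)
from nucpatch.traces import Trace

from conftest import species_model


def na_only_patch(gmax=100.0, species="human", **kw):
    na = species_preset(f"{species}_na").with_gmax(gmax)
    kw.setdefault("gleak", 0.0)
    return PatchModel(na_channels=(na,), **kw)


class TestIntegrate:
    def test_passive_compartment_settles_to_eleak(self):
        model = PatchModel(gleak=1.0, eleak=-72.0)
        stim = Trace(np.zeros(4000), 0.025, units="pA")
        out = integrate(model, stim, mode="free", v0=-40.0)
        assert out.v.values[-1] == pytest.approx(-72.0, abs=1e-3)

    def test_clamped_gate_follows_closed_form_relaxation(self):
        """Under voltage clamp at fixed V the exponential-update integrator
        reproduces x(t) = xinf + (x0 - xinf) e^(-t/tau) exactly."""
        model = na_only_patch()
        gate = model.na_channels[0].h
        v_hold, v_step = -90.0, -50.0
        dt = 0.02
        cmd = Trace(np.full(5000, v_step), dt, units="mV")
        res = integrate(model, cmd, mode="clamp", v0=v_hold)
        h = res.na_gates[:, 1]
        t = dt * (1 + np.arange(h.size))  # gates updated before sample t
        x0 = steady_state(v_hold, gate)
        xinf = steady_state(v_step, gate)
        tau = time_constant(v_step, gate)
        exact = xinf + (x0 - xinf) * np.exp(-t / tau)
        assert np.max(np.abs(h - exact)) < 1e-9

    def test_determinism_bit_identical(self):
        model = species_model("human", 400.0, 70.0)
        stim = Trace(np.r_[np.zeros(200), np.full(120, 80.0), np.zeros(800)],
                     0.025, units="pA")
        a = integrate(model, stim, mode="free")
        b = integrate(model, stim, mode="free")
        assert np.array_equal(a.v.values, b.v.values)
        assert np.array_equal(a.h_na.values, b.h_na.values)

    def test_dt_convergence_of_peak_na_current(self):
        """Halving dt changes the peak Na+ current by < 0.5%."""
        model = na_only_patch(gmax=100.0)
        peaks = {}
        for dt in (0.01, 0.005):
            n_hold = int(20 / dt)
            cmd = Trace(np.r_[np.full(n_hold, -90.0), np.full(int(20 / dt), -10.0)],
                        dt, units="mV")
            res = integrate(model, cmd, mode="clamp")
            peaks[dt] = np.min(res.i_na)
        assert abs(peaks[0.005] - peaks[0.01]) < 0.005 * abs(peaks[0.005])

    def test_ap_peak_time_converged_at_default_dt(self):
        model = species_model("human", 400.0, 70.0)
        t_pk = {}
        for dt in (0.025, 0.0125):
            out = simulate_ap_train(model, freq=40.0, n_aps=1, amp=150.0, dt=dt)
            t_pk[dt] = out.v.t[np.argmax(out.v.values)]
        assert abs(t_pk[0.025] - t_pk[0.0125]) <= 0.025 + 1e-9

    def test_clamp_decomposition_sums_to_total(self):
        model = species_model("human", 100.0, 50.0)
        cmd = Trace(np.r_[np.full(1000, -90.0), np.full(1000, 0.0)], 0.02,
                    units="mV")
        res = integrate(model, cmd, mode="clamp")
        assert np.allclose(
            res.i_total, res.i_na + res.i_k + res.i_leak + res.i_cap
        )

    def test_clamp_replay_of_free_run_recovers_injected_current(self):
        """Replaying a free-run voltage as the clamp command returns a total
        membrane current that converges (first order in dt) to the current
        that was injected."""
        model = species_model("human", 400.0, 70.0)
        errs = {}
        for dt in (0.01, 0.005):
            out = simulate_ap_train(model, freq=40.0, n_aps=2, amp=150.0, dt=dt)
            res = integrate(model, out.v, mode="clamp")
            t = out.v.t
            inj = np.zeros_like(t)
            for k in range(2):
                inj[(t >= 5 + 25 * k) & (t < 8 + 25 * k)] = 150.0
            errs[dt] = np.max(np.abs(res.i_total - inj)) / np.max(np.abs(res.i_na))
        assert errs[0.005] < 0.08
        assert errs[0.005] < 0.7 * errs[0.01]

    def test_nan_stimulus_rejected(self):
        model = PatchModel()
        stim = Trace(np.array([0.0, np.nan, 0.0]), 0.025, units="pA")
        with pytest.raises(ValueError):
            integrate(model, stim)


class TestProtocols:
    def test_activation_curve_equals_minf_cubed_without_inactivation(self):
        """With inactivation disabled (tau_h -> inf, h ~ 1) the measured
        activation curve is m_inf(V)^p renormalized."""
        na = species_preset("human_na")
        slow_h = GateSpec(
            -66.0, 7.0, "inactivation", (1e-9, 1e-9, -45.0, -60.0, 6.0, 7.0)
        )
        ch = NaChannelModel(gmax=100.0, m=na.m, h=slow_h, p=na.p)
        model = PatchModel(na_channels=(ch,), gleak=0.0)
        steps = np.arange(-80.0, 41.0, 10.0)
        v, g, _ = steady_state_activation_protocol(model, steps=steps, dt=0.01)
        expected = steady_state(v, na.m) ** na.p
        expected = expected / expected.max()
        assert np.max(np.abs(np.abs(g) - expected)) < 0.01

    def test_activation_curve_monotone_and_zero_at_hyperpolarized(self):
        model = na_only_patch()
        v, g, _ = steady_state_activation_protocol(model, dt=0.01)
        g = np.abs(g)
        assert g[0] < 0.01
        assert np.all(np.diff(g) > -0.01)

    def test_reversal_step_excluded(self):
        model = na_only_patch()
        steps = np.array([-40.0, model.ena, 60.0])
        v, g, _ = steady_state_activation_protocol(model, steps=steps, dt=0.01)
        assert model.ena not in v

    def test_availability_curve_equals_hinf(self):
        """Equilibrating prepulses make the availability curve track the
        steady-state inactivation Boltzmann; midpoint availability 0.5."""
        model = na_only_patch()
        gate = model.na_channels[0].h
        pre = np.arange(-120.0, -29.0, 10.0)
        v, avail, _ = steady_state_inactivation_protocol(
            model, prepulses=pre, dt=0.02
        )
        hinf = steady_state(v, gate)
        hinf = hinf / hinf.max()
        assert np.max(np.abs(avail - hinf)) < 0.01
        assert avail[0] > 0.99  # full availability at -120 mV
        mid = np.interp(gate.vhalf, v, avail)
        assert mid == pytest.approx(0.5, abs=0.02)

    def test_recovery_tau_matches_gate_time_constant(self):
        """Fitted recovery time constant equals tau_h at the recovery
        potential within 1% for a single-h-gate channel."""
        model = na_only_patch()
        gate = model.na_channels[0].h
        for vrec in (-80.0, -100.0):
            delays = np.geomspace(0.5, 8 * time_constant(vrec, gate), 10)
            d, frac, tau = recovery_protocol(
                model, vrec=vrec, delays=delays, dt=0.02
            )
            assert tau == pytest.approx(time_constant(vrec, gate), rel=0.01)
            # long-delay limit: full recovery relative to the rested
            # reference peak measured from the same recovery potential
            assert frac[-1] == pytest.approx(1.0, abs=0.02)
            assert frac[0] < frac[-1]

    def test_protocol_grid_validation(self):
        with pytest.raises(ValueError):
            ProtocolSpec(mode="recovery", delays=(5.0, 1.0, 10.0))


class TestAPClamp:
    def test_first_amplitude_normalized_to_one(self, ap_command):
        cmd, peaks = ap_command
        model = na_only_patch(gmax=100.0)
        amps, _ = ap_clamp(model, cmd, peaks)
        assert amps[0] == 1.0
        assert amps.size == peaks.size

    def test_instantaneous_gates_have_no_history(self, ap_command):
        """With near-instantaneous kinetics every AP evokes the same
        current: all normalized amplitudes are ~1."""
        cmd, peaks = ap_command
        na = species_preset("human_na")
        fast_m = na.m.with_(kin=(50.0, 50.0, -38.0, 10.0))
        fast_h = na.h.with_(kin=(5.0, 5.0, -45.0, -60.0, 6.0, 7.0))
        ch = NaChannelModel(gmax=100.0, m=fast_m, h=fast_h, p=na.p)
        model = PatchModel(na_channels=(ch,), gleak=0.0)
        amps, _ = ap_clamp(model, cmd, peaks)
        assert np.max(np.abs(amps - 1.0)) < 0.02

    def test_human_na_more_stable_than_mouse(self, ap_command):
        cmd, peaks = ap_command
        a = {}
        for sp in ("human", "mouse"):
            model = na_only_patch(gmax=100.0, species=sp)
            amps, _ = ap_clamp(model, cmd, peaks)
            a[sp] = amps
        assert a["human"][4] > a["mouse"][4]

    def test_ap_times_outside_trace_rejected(self, ap_command):
        cmd, peaks = ap_command
        model = na_only_patch()
        with pytest.raises(ValueError):
            ap_clamp(model, cmd, np.append(peaks, cmd.t0 + cmd.duration + 5.0))


class TestRheobaseAndTrains:
    def test_bisection_equals_exhaustive_scan(self):
        model = species_model("human", 400.0, 70.0)
        precision = 20.0
        rb = find_rheobase(model, precision=precision, max_amp=2000.0)
        # brute force over the same grid
        from nucpatch.simulator import _has_ap

        grid = np.arange(precision, 2000.0 + precision, precision)
        brute = next(a for a in grid if _has_ap(model, a, 3.0, 0.025))
        assert rb == brute
        assert rb % precision == 0

    def test_more_sodium_lowers_rheobase(self):
        rbs = [
            find_rheobase(species_model("human", g, 70.0), precision=1.0)
            for g in (300.0, 500.0, 800.0)
        ]
        assert rbs[0] > rbs[1] > rbs[2]

    def test_no_ap_raises(self):
        model = PatchModel(gleak=1.0)  # passive: cannot reach threshold
        with pytest.raises(RuntimeError):
            find_rheobase(model, max_amp=50.0)

    def test_train_protocol_contract(self):
        model = species_model("human", 400.0, 70.0)
        out = simulate_ap_train(model, freq=40.0, n_aps=5)
        from nucpatch.apshape import detect_threshold

        dets = detect_threshold(out.v)
        assert len(dets) == 5
        intervals = np.diff([d.t_peak for d in dets])
        assert np.allclose(intervals, 25.0, atol=0.5)

    def test_single_ap_stability_is_unity(self):
        from nucpatch.apshape import train_stability

        model = species_model("human", 400.0, 70.0)
        out = simulate_ap_train(model, freq=40.0, n_aps=1)
        stab = train_stability(out.v, 1)
        assert stab.rel_rise.tolist() == [1.0]

    def test_failed_pulses_reported(self):
        model = species_model("human", 400.0, 70.0)
        with pytest.raises(RuntimeError, match="indices"):
            simulate_ap_train(model, freq=40.0, n_aps=3, amp=5.0)

    def test_interval_narrower_than_pulse_rejected(self):
        model = species_model("human", 400.0, 70.0)
        with pytest.raises(ValueError):
            simulate_ap_train(model, freq=400.0, n_aps=2, pulse_ms=3.0)
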