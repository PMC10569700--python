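"""AP threshold detection, waveform features, train stability, bootstrap."""

import numpy as np
import pytest

from nucpatch.apshape import (
    DVDT_THRESHOLD,
    analyze_train,
    ap_features,
    bootstrap_ci,
    detect_threshold,
    train_stability,
)
from nucpatch.simulator import simulate_ap_train
from nucpatch.traces import Trace

from conftest import species_model


def _ramp(v0, v1, slope, dt):
    """Samples after v0 (exclusive) climbing to v1 at exactly |slope| mV/ms
    per consecutive sample pair."""
    n = max(1, int(round(abs(v1 - v0) / (slope * dt))))
    step = np.sign(v1 - v0) * slope * dt
    return v0 + step * np.arange(1, n + 1)


def synthetic_spike(dt=0.01, v_rest=-70.0, slope=400.0):
    """Piecewise-linear spike: slow ramp (10 mV/ms, below the 23 mV/ms
    criterion) to -50 mV, fast linear upstroke to +20 mV at exactly
    ``slope``, downstroke at exactly 100 mV/ms, return to rest.  The
    threshold crossing is the corner sample at -50 mV by construction."""
    up_from = -50.0
    seg0 = np.full(int(5 / dt), v_rest)
    seg1 = _ramp(v_rest, up_from, 10.0, dt)
    seg2 = _ramp(seg1[-1], 20.0, slope, dt)
    seg3 = _ramp(seg2[-1], v_rest, 100.0, dt)
    seg4 = np.full(int(5 / dt), v_rest)
    v = np.concatenate([seg0, seg1, seg2, seg3, seg4])
    i_cross = seg0.size + seg1.size  # first sample of the fast upstroke
    return Trace(v, dt, units="mV"), i_cross


class TestThresholdDetection:
    def test_constructed_crossing_found_exactly(self):
        tr, i_cross = synthetic_spike()
        dets = detect_threshold(tr)
        assert len(dets) == 1
        # central differences smear the corner across one sample
        assert abs(dets[0].i_threshold - i_cross) <= 1
        assert dets[0].v_threshold == pytest.approx(-50.0, abs=1.0)

    def test_subthreshold_trace_empty(self):
        t = np.arange(0, 50, 0.01)
        tr = Trace(-70.0 + 5.0 * np.sin(t), 0.01, units="mV")
        assert detect_threshold(tr) == []

    def test_matches_exhaustive_scan_on_simulated_aps(self):
        """The detector reproduces a brute-force scan of the 23 mV/ms rule
        over all samples of a simulated train."""
        model = species_model("human", 400.0, 70.0)
        out = simulate_ap_train(model, freq=40.0, n_aps=4)
        v = out.v.values
        dvdt = np.gradient(v, out.v.dt)
        dets = detect_threshold(out.v)
        assert len(dets) == 4
        for det in dets:
            # brute force: last i <= argmax(dvdt in upstroke) with an
            # upward crossing of the criterion
            seg_start = 0
            for other in dets:
                if other.i_peak < det.i_peak:
                    seg_start = other.i_peak
            i_dvdt_max = seg_start + int(
                np.argmax(dvdt[seg_start : det.i_peak + 1])
            )
            brute = None
            for i in range(i_dvdt_max, seg_start, -1):
                if dvdt[i] >= DVDT_THRESHOLD and dvdt[i - 1] < DVDT_THRESHOLD:
                    brute = i
                    break
            assert det.i_threshold == brute


class TestFeatures:
    def test_linear_upstroke_speed_both_estimators(self):
        tr, _ = synthetic_spike(slope=400.0)
        dets = detect_threshold(tr)
        f = ap_features(tr, dets[0])
        assert f.rise_speed == pytest.approx(400.0, rel=0.02)
        assert f.rise_speed_fit == pytest.approx(400.0, rel=0.02)
        assert f.fall_speed == pytest.approx(100.0, rel=0.05)
        assert f.fall_speed_fit == pytest.approx(100.0, rel=0.05)

    def test_amplitude_threshold_to_peak(self):
        tr, _ = synthetic_spike()
        f = ap_features(tr, detect_threshold(tr)[0])
        assert f.amplitude == f.peak_v - f.threshold_v
        assert f.amplitude == pytest.approx(70.0, abs=2.5)  # -50 -> +20 mV

    def test_dc_offset_invariance(self):
        tr, _ = synthetic_spike()
        shifted = Trace(tr.values + 7.0, tr.dt, units="mV")
        f0 = ap_features(tr, detect_threshold(tr)[0])
        f1 = ap_features(shifted, detect_threshold(shifted)[0])
        assert f1.rise_speed == pytest.approx(f0.rise_speed, rel=1e-6)
        assert f1.fall_speed == pytest.approx(f0.fall_speed, rel=1e-6)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=0.5)

    def test_resampling_tolerance(self):
        tr, _ = synthetic_spike(dt=0.01)
        fine, _ = synthetic_spike(dt=0.005)
        f0 = ap_features(tr, detect_threshold(tr)[0])
        f1 = ap_features(fine, detect_threshold(fine)[0])
        assert f1.rise_speed == pytest.approx(f0.rise_speed, rel=0.03)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=2.5)

    def test_estimator_variants_preserve_rank_on_simulated_aps(self):
        """Max-derivative and 30-70%-window rise estimators rank simulated
        APs of different Na+ densities identically."""
        deriv, fitv = [], []
        for g_na in (250.0, 350.0, 500.0, 800.0):
            model = species_model("human", g_na, 70.0)
            out = simulate_ap_train(model, freq=40.0, n_aps=1, amp=150.0)
            f = analyze_train(out.v)[0]
            deriv.append(f.rise_speed)
            fitv.append(f.rise_speed_fit)
        assert np.argsort(deriv).tolist() == np.argsort(fitv).tolist()


class TestTrainStability:
    def test_identical_aps_give_unity_ratios(self):
        one, _ = synthetic_spike()
        v = np.tile(one.values, 5)
        tr = Trace(v, one.dt, units="mV")
        stab = train_stability(tr, 5)
        assert np.allclose(stab.rel_rise, 1.0, atol=1e-9)
        assert np.allclose(stab.rel_fall, 1.0, atol=1e-9)

    def test_injected_monotone_decay_recovered(self):
        parts = []
        scales = [1.0, 0.9, 0.8, 0.7]
        for s in scales:
            spike, _ = synthetic_spike(slope=400.0 * s)
            parts.append(spike.values)
        tr = Trace(np.concatenate(parts), 0.01, units="mV")
        stab = train_stability(tr, 4)
        assert np.all(np.diff(stab.rel_rise) < 0)
        assert stab.rel_rise[-1] == pytest.approx(0.7, abs=0.03)

    def test_missing_ap_reports_index(self):
        one, _ = synthetic_spike()
        tr = Trace(np.tile(one.values, 3), one.dt, units="mV")
        with pytest.raises(RuntimeError, match="expected 5, detected 3"):
            train_stability(tr, 5)

    def test_human_train_rise_more_stable_than_mouse(self, species_trains):
        """At their own fitted densities, 70-Hz/200-AP trains keep a larger
        fraction of the initial rise speed with human channels."""
        stabs = {
            sp: train_stability(out.v, 200) for sp, out in species_trains.items()
        }
        assert stabs["human"].rel_rise[4] > stabs["mouse"].rel_rise[4]
        assert stabs["human"].rel_rise[199] > stabs["mouse"].rel_rise[199]


class TestBootstrap:
    def test_constant_samples_zero_width(self):
        lo, hi = bootstrap_ci([3.0] * 10, seed=0)
        assert lo == hi == 3.0

    def test_interval_contains_sample_mean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10.0, 2.0, 40)
        lo, hi = bootstrap_ci(x, seed=1)
        assert lo < np.mean(x) < hi

    def test_coverage_near_nominal(self):
        """~95% of bootstrap CIs over repeated Gaussian cohorts cover the
        true mean."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(0.0, 1.0, 25)
            lo, hi = bootstrap_ci(x, n_boot=600, seed=rng.integers(2**31))
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / n_rep <= 0.99

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])
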