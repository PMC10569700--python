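"""Action-potential waveform features and train-stability metrics.

Threshold is the classic derivative criterion: the voltage at the last
time dV/dt crosses 23 mV/ms (upward) before the dV/dt maximum of each AP.
Rise and fall speed come in two flavours each: the extremum of the
derivative, and the slope of a line fitted within 30-70% (70-30%) of the
AP amplitude.  Traces marked ``meta["raw"] = True`` are low-pass filtered
at 20 kHz before differentiation; clean model output is used as is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .fits import lowpass
from .traces import Trace

__all__ = [
    "APFeatures",
    "TrainStability",
    "detect_threshold",
    "ap_features",
    "train_stability",
    "bootstrap_ci",
    "DVDT_THRESHOLD",
]

DVDT_THRESHOLD = 23.0  # mV/ms
PEAK_MIN_V = 0.0  # mV: AP peak = local maximum above this


@dataclass(frozen=True)
class APDetection:
    """Per-AP threshold/peak sample bookkeeping (times in ms, absolute)."""

    i_threshold: int
    t_threshold: float
    v_threshold: float
    i_peak: int
    t_peak: float
    v_peak: float


@dataclass(frozen=True)
class APFeatures:
    threshold_v: float
    peak_v: float
    amplitude: float  # threshold -> peak, mV
    rise_speed: float  # max dV/dt, mV/ms
    fall_speed: float  # |min dV/dt|, mV/ms (positive magnitude)
    rise_speed_fit: float  # 30-70% linear-fit variant
    fall_speed_fit: float  # 70-30% linear-fit variant
    t_peak: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrainStability:
    """Per-AP rise/fall speeds normalized to the first AP (first entry 1)."""

    rel_rise: np.ndarray
    rel_fall: np.ndarray
    frequency: float
    features: tuple[APFeatures, ...]

    def at(self, n: int) -> tuple[float, float]:
        """(relative rise, relative fall) of the n-th AP (1-based)."""
        return float(self.rel_rise[n - 1]), float(self.rel_fall[n - 1])


def _dvdt(v: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative (one-sided at the edges)."""
    return np.gradient(v, dt)


def _prepare(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    tr = trace
    if trace.meta.get("raw"):
        tr = lowpass(trace, 20.0)
    v = tr.values
    return v, _dvdt(v, tr.dt)


def detect_threshold(trace: Trace) -> list[APDetection]:
    """Detect APs and their thresholds in a voltage trace.

    APs are segmented at local maxima above 0 mV; within each AP's
    upstroke, the threshold sample is the last upward crossing of the 23
    mV/ms derivative criterion before the dV/dt maximum.  Returns an empty
    list for subthreshold traces.
    """
    v, dvdt = _prepare(trace)
    dt, t0 = trace.dt, trace.t0
    peaks, _ = find_peaks(v, height=PEAK_MIN_V)
    out: list[APDetection] = []
    prev_peak = 0
    for pk in peaks:
        # dV/dt maximum of this AP's upstroke: between the previous peak
        # (or trace start) and this peak
        seg0 = prev_peak
        i_dvdt_max = seg0 + int(np.argmax(dvdt[seg0 : pk + 1]))
        # last upward crossing: indices i in (seg0, i_dvdt_max] with
        # dvdt[i] >= thr and dvdt[i-1] < thr
        idx = np.arange(seg0 + 1, i_dvdt_max + 1)
        if idx.size:
            up = (dvdt[idx] >= DVDT_THRESHOLD) & (dvdt[idx - 1] < DVDT_THRESHOLD)
            cand = idx[up]
        else:
            cand = np.array([], dtype=int)
        if cand.size == 0:
            # derivative never dips below the criterion in the segment
            # (e.g. first AP riding a fast stimulus): fall back to the
            # first sample at/above the criterion
            at = np.nonzero(dvdt[seg0 : i_dvdt_max + 1] >= DVDT_THRESHOLD)[0]
            if at.size == 0:
                prev_peak = pk
                continue
            i_thr = seg0 + int(at[0])
        else:
            i_thr = int(cand[-1])
        out.append(
            APDetection(
                i_threshold=i_thr,
                t_threshold=t0 + i_thr * dt,
                v_threshold=float(v[i_thr]),
                i_peak=int(pk),
                t_peak=t0 + pk * dt,
                v_peak=float(v[pk]),
            )
        )
        prev_peak = pk
    return out


def _linfit_speed(t: np.ndarray, v: np.ndarray) -> float:
    if t.size < 3:
        return np.nan
    return float(np.polyfit(t, v, 1)[0])


def ap_features(
    trace: Trace, det: APDetection, next_i: int | None = None
) -> APFeatures:
    """Extract waveform features for one detected AP.

    ``next_i`` bounds the falling phase (index of the next AP threshold or
    trace end).  Amplitude is defined threshold -> peak.  The 30-70%
    window variants are flagged when they contain fewer than 3 samples.
    """
    v, dvdt = _prepare(trace)
    dt = trace.dt
    i_thr, i_pk = det.i_threshold, det.i_peak
    i_end = len(v) if next_i is None else next_i

    amplitude = det.v_peak - det.v_threshold
    rise = float(np.max(dvdt[i_thr : i_pk + 1]))
    # falling phase: from the peak until V returns to threshold (or segment end)
    fall_seg = v[i_pk:i_end]
    below = np.nonzero(fall_seg <= det.v_threshold)[0]
    i_fall_end = i_pk + (int(below[0]) + 1 if below.size else fall_seg.size)
    fall = float(-np.min(dvdt[i_pk:i_fall_end]))

    lo = det.v_threshold + 0.3 * amplitude
    hi = det.v_threshold + 0.7 * amplitude
    flags: tuple[str, ...] = ()

    t = np.arange(len(v)) * dt
    rise_mask = slice(i_thr, i_pk + 1)
    rw = (v[rise_mask] >= lo) & (v[rise_mask] <= hi)
    rise_fit = _linfit_speed(t[rise_mask][rw], v[rise_mask][rw])
    fall_mask = slice(i_pk, i_fall_end)
    fw = (v[fall_mask] >= lo) & (v[fall_mask] <= hi)
    fall_fit = -_linfit_speed(t[fall_mask][fw], v[fall_mask][fw])
    if np.isnan(rise_fit) or np.isnan(fall_fit):
        flags += ("fit_window_short",)

    return APFeatures(
        threshold_v=det.v_threshold,
        peak_v=det.v_peak,
        amplitude=amplitude,
        rise_speed=rise,
        fall_speed=fall,
        rise_speed_fit=rise_fit,
        fall_speed_fit=fall_fit,
        t_peak=det.t_peak,
        flags=flags,
    )


def analyze_train(trace: Trace) -> list[APFeatures]:
    """Features for every AP detected in the trace, in order."""
    dets = detect_threshold(trace)
    feats = []
    for k, det in enumerate(dets):
        next_i = dets[k + 1].i_threshold if k + 1 < len(dets) else None
        feats.append(ap_features(trace, det, next_i))
    return feats


def train_stability(train: Trace, n_aps: int, frequency: float = np.nan) -> TrainStability:
    """Per-AP rise/fall speeds relative to AP1 for an evoked train.

    Raises when fewer than ``n_aps`` APs are detected, reporting the first
    missing index.
    """
    feats = analyze_train(train)
    if len(feats) < n_aps:
        raise RuntimeError(
            f"missed AP: expected {n_aps}, detected {len(feats)} "
            f"(first missing index {len(feats)})"
        )
    feats = feats[:n_aps]
    rise = np.array([f.rise_speed for f in feats])
    fall = np.array([f.fall_speed for f in feats])
    return TrainStability(
        rel_rise=rise / rise[0],
        rel_fall=fall / fall[0],
        frequency=float(train.meta.get("freq_hz", frequency)),
        features=tuple(feats),
    )


def bootstrap_ci(
    samples: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.mean,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval for ``stat``."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    reps = np.apply_along_axis(stat, 1, x[idx])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(reps, alpha)),
        float(np.quantile(reps, 1.0 - alpha)),
    )
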