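"""Single-compartment nucleated-patch simulator and voltage-clamp protocols.

The compartment is an isopotential sphere (default diameter 10 um, membrane
area pi*d^2) carrying up to four Hodgkin-Huxley channel populations (human
and mouse Na+ and K+) plus an ohmic leak.  Three operating modes:

* current clamp ("free"): injected current in pA, membrane potential
  integrated;
* voltage clamp: arbitrary command waveform, total membrane current
  recorded with its ionic / leak / capacitive decomposition;
* AP clamp: voltage clamp replaying an action-potential train command,
  with per-AP peak-current bookkeeping.

On top of the raw integrator sit the standard square-pulse protocol
batteries (steady-state activation and inactivation, kinetics steps,
recovery from inactivation), rheobase search and evoked AP trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import _kernel
from .gates import (
    ChannelMix,
    GateSpec,
    KChannelModel,
    NaChannelModel,
    mixed_densities,
    steady_state,
)
from .traces import Trace

__all__ = [
    "PatchModel",
    "ProtocolSpec",
    "SimResult",
    "ClampResult",
    "integrate",
    "steady_state_activation_protocol",
    "steady_state_inactivation_protocol",
    "recovery_protocol",
    "ap_clamp",
    "find_rheobase",
    "simulate_ap_train",
]


@dataclass(frozen=True)
class PatchModel:
    """Spherical single compartment with a set of Na+/K+ channel models.

    Defaults reproduce the standard configuration: 10 um diameter, 1
    uF cm^-2, ENa 53 mV, EK -101 mV, leak 1 pS um^-2 to -80 mV (the
    junction-corrected resting potential of the current-clamp recordings;
    at -80 mV the preset channels reproduce the reported resting Na+
    availabilities, ~0.81 human vs ~0.63 mouse).  For long
    phase-locking runs the convention is gleak 2.5 pS um^-2 and ENa 100 mV
    (see :meth:`phase_locking_variant`), which prevents depolarization
    block during sustained stimulation.
    """

    na_channels: tuple[NaChannelModel, ...] = ()
    k_channels: tuple[KChannelModel, ...] = ()
    diameter: float = 10.0  # um
    cm: float = 1.0  # uF cm^-2
    ra: float = 200.0  # ohm cm (unused in a single compartment; kept for record)
    ena: float = 53.0  # mV
    ek: float = -101.0  # mV
    gleak: float = 1.0  # pS um^-2
    eleak: float = -80.0  # mV (junction-corrected resting potential)

    @property
    def area(self) -> float:
        """Membrane area in um^2 (sphere: pi * d^2)."""
        return math.pi * self.diameter**2

    @property
    def c_pf(self) -> float:
        """Total capacitance in pF (1 uF cm^-2 == 0.01 pF um^-2)."""
        return self.cm * 0.01 * self.area

    @property
    def gleak_ns(self) -> float:
        return self.gleak * self.area * 1e-3

    def phase_locking_variant(self) -> "PatchModel":
        """Copy with the long-simulation constants (gleak 2.5, ENa 100)."""
        return replace(self, gleak=2.5, ena=100.0)

    @classmethod
    def from_mix(
        cls,
        mix: ChannelMix,
        na_human: NaChannelModel,
        na_mouse: NaChannelModel,
        k_human: KChannelModel,
        k_mouse: KChannelModel,
        **constants,
    ) -> "PatchModel":
        """Build a hybrid-patch model from total densities + human fractions."""
        d = mixed_densities(mix)
        na = tuple(
            ch.with_gmax(g)
            for ch, g in ((na_human, d["na_human"]), (na_mouse, d["na_mouse"]))
            if g > 0
        )
        k = tuple(
            ch.with_gmax(g)
            for ch, g in ((k_human, d["k_human"]), (k_mouse, d["k_mouse"]))
            if g > 0
        )
        return cls(na_channels=na, k_channels=k, **constants)


@dataclass(frozen=True)
class ProtocolSpec:
    """Square-pulse voltage-clamp protocol description.

    Grids are in mV and must be monotone; durations in ms.  Defaults follow
    common practice: activation steps -80..+60 mV from -90 mV holding,
    inactivation prepulses -120..-30 mV for 500 ms with a 0 mV test pulse,
    recovery delays log-spaced 1-300 ms.
    """

    mode: Literal[
        "steady_activation",
        "steady_inactivation",
        "kinetics",
        "recovery",
        "ap_clamp",
        "current_clamp",
    ]
    holding: float = -90.0
    steps: tuple[float, ...] = tuple(np.arange(-80.0, 61.0, 10.0))
    prepulses: tuple[float, ...] = tuple(np.arange(-120.0, -29.0, 10.0))
    vtest: float = 0.0
    prepulse_ms: float = 500.0
    step_ms: float = 50.0
    delays: tuple[float, ...] = tuple(np.geomspace(1.0, 300.0, 10))

    def __post_init__(self):
        for grid in (self.steps, self.prepulses, self.delays):
            if len(grid) > 1 and np.any(np.diff(grid) <= 0):
                raise ValueError("protocol grids must be strictly increasing")
        if self.prepulse_ms < 0 or self.step_ms < 0:
            raise ValueError("durations must be >= 0")


# ---------------------------------------------------------------------------
# packing & state helpers


def _pack_na(ch: NaChannelModel) -> np.ndarray:
    row = np.empty(_kernel.NA_ROW)
    row[0] = ch.gmax
    row[1] = ch.p
    row[2], row[3] = ch.m.vhalf, ch.m.q
    row[4:8] = ch.m.kin
    row[8], row[9] = ch.h.vhalf, ch.h.q
    row[10:16] = ch.h.kin
    return row


def _pack_k(ch: KChannelModel) -> np.ndarray:
    row = np.empty(_kernel.K_ROW)
    row[0] = ch.gmax
    row[1], row[2] = ch.m.vhalf, ch.m.q
    row[3:7] = ch.m.kin
    row[7], row[8] = ch.h1.vhalf, ch.h1.q
    row[9:15] = ch.h1.kin
    row[15], row[16] = ch.h2.kin
    row[17], row[18] = ch.frac_inact, ch.frac_h2
    return row


def _pack(model: PatchModel) -> tuple[np.ndarray, np.ndarray]:
    na_p = (
        np.stack([_pack_na(c) for c in model.na_channels])
        if model.na_channels
        else np.empty((0, _kernel.NA_ROW))
    )
    k_p = (
        np.stack([_pack_k(c) for c in model.k_channels])
        if model.k_channels
        else np.empty((0, _kernel.K_ROW))
    )
    return na_p, k_p


def _init_states(model: PatchModel, v: float) -> tuple[np.ndarray, np.ndarray]:
    """Gate states at their steady values for voltage ``v``."""
    na_s = np.empty((len(model.na_channels), 2))
    for i, ch in enumerate(model.na_channels):
        na_s[i, 0] = steady_state(v, ch.m)
        na_s[i, 1] = steady_state(v, ch.h)
    k_s = np.empty((len(model.k_channels), 3))
    for i, ch in enumerate(model.k_channels):
        k_s[i, 0] = steady_state(v, ch.m)
        k_s[i, 1] = steady_state(v, ch.h1)
        k_s[i, 2] = steady_state(v, ch.h2)
    return na_s, k_s


@dataclass
class SimResult:
    """Current-clamp result: membrane potential + Na availability series."""

    v: Trace
    h_na: Trace


@dataclass
class ClampResult:
    """Voltage-clamp result with current decomposition and gate series."""

    command: Trace
    i_na: np.ndarray
    i_k: np.ndarray
    i_leak: np.ndarray
    i_cap: np.ndarray
    na_gates: np.ndarray  # (n, 2 * n_na): m, h per population
    k_gates: np.ndarray  # (n, 3 * n_k): m, h1, h2 per population

    @property
    def i_total(self) -> np.ndarray:
        return self.i_na + self.i_k + self.i_leak + self.i_cap

    @property
    def i_ionic(self) -> np.ndarray:
        return self.i_na + self.i_k

    @property
    def dt(self) -> float:
        return self.command.dt


def integrate(
    model: PatchModel,
    stimulus: Trace,
    mode: Literal["free", "clamp"] = "free",
    v0: float | None = None,
    settle_ms: float = 200.0,
):
    """Integrate the compartment against a stimulus.

    Parameters
    ----------
    stimulus : Trace
        In ``free`` mode the injected current (pA); in ``clamp`` mode the
        command voltage (mV).  The stimulus ``dt`` sets the integration
        step.
    v0 : float, optional
        Initial membrane potential; defaults to ``eleak`` (free) or the
        first command sample (clamp).  Gates start at steady state for v0.
    settle_ms : float
        Free mode only: settle period at zero input prepended (and
        discarded) before the stimulus so the model starts from its resting
        state.  Deterministic for fixed inputs.

    Returns
    -------
    SimResult (free) or ClampResult (clamp).
    """
    dt = stimulus.dt
    values = np.ascontiguousarray(stimulus.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("stimulus contains non-finite samples")
    na_p, k_p = _pack(model)

    if mode == "clamp":
        v_start = float(values[0]) if v0 is None else v0
        na_s, k_s = _init_states(model, v_start)
        i_na, i_k, i_leak, i_cap, na_g, k_g = _kernel.run_clamp(
            values, na_p, k_p, na_s, k_s,
            model.area, model.c_pf, model.ena, model.ek,
            model.gleak_ns, model.eleak, dt,
        )
        return ClampResult(stimulus, i_na, i_k, i_leak, i_cap, na_g, k_g)

    if mode != "free":
        raise ValueError(f"unknown mode {mode!r}")
    v_start = model.eleak if v0 is None else v0
    na_s, k_s = _init_states(model, v_start)
    n_settle = int(round(settle_ms / dt))
    if n_settle:
        v_set, _ = _kernel.run_free(
            v_start, na_p, k_p, na_s, k_s, model.area, model.c_pf,
            model.ena, model.ek, model.gleak_ns, model.eleak,
            np.zeros(n_settle), dt,
        )
        v_start = v_set[-1]
    v, h = _kernel.run_free(
        v_start, na_p, k_p, na_s, k_s, model.area, model.c_pf,
        model.ena, model.ek, model.gleak_ns, model.eleak, values, dt,
    )
    return SimResult(
        v=Trace(v, dt, t0=stimulus.t0, units="mV", meta=dict(stimulus.meta)),
        h_na=Trace(h, dt, t0=stimulus.t0, units="1", meta={"series": "h_na"}),
    )


# ---------------------------------------------------------------------------
# voltage-clamp protocol battery


def _step_command(holding, levels_durations, dt) -> Trace:
    segs = [np.full(max(1, int(round(d / dt))), float(v)) for v, d in levels_durations]
    vals = np.concatenate([[holding], *segs])
    return Trace(vals, dt, units="mV")


def _ionic_current(res: ClampResult, ion: str) -> np.ndarray:
    return res.i_na if ion == "na" else res.i_k


def steady_state_activation_protocol(
    model: PatchModel,
    steps: Sequence[float] | None = None,
    holding: float = -90.0,
    step_ms: float = 50.0,
    dt: float = 0.01,
    ion: str = "na",
):
    """Steady-state activation curve from voltage steps.

    For each step the peak (Na+) or late steady (K+) ionic current is
    converted to conductance G = I / (V - Erev) and the curve normalized to
    its maximum.  Steps within 1 mV of the reversal potential are excluded
    (division blow-up).

    Returns
    -------
    (v_used, g_norm, traces) : voltages, normalized conductances, and the
    per-step :class:`ClampResult` list.
    """
    if steps is None:
        steps = np.arange(-80.0, 61.0, 10.0)
    erev = model.ena if ion == "na" else model.ek
    v_used, g, traces = [], [], []
    for v_step in steps:
        if abs(v_step - erev) < 1.0:
            continue
        cmd = _step_command(holding, [(holding, 20.0), (v_step, step_ms)], dt)
        res = integrate(model, cmd, mode="clamp", v0=holding)
        i = _ionic_current(res, ion)
        n0 = len(cmd) - int(round(step_ms / dt))
        seg = i[n0:]
        if ion == "na":
            i_meas = seg[np.argmax(np.abs(seg))]
        else:
            i_meas = np.mean(seg[int(0.9 * seg.size):])  # late plateau
        v_used.append(v_step)
        g.append(i_meas / (v_step - erev))
        traces.append(res)
    g = np.asarray(g)
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise ValueError("no conductance activated over the step grid")
    return np.asarray(v_used), g / gmax, traces


def steady_state_inactivation_protocol(
    model: PatchModel,
    prepulses: Sequence[float] | None = None,
    vtest: float = 0.0,
    prepulse_ms: float = 500.0,
    test_ms: float = 30.0,
    dt: float = 0.01,
    ion: str = "na",
):
    """Availability curve: normalized peak test-pulse current vs prepulse V.

    The prepulse (default 500 ms) equilibrates inactivation at each level
    before a fixed test step.  Returns (prepulse_v, availability, traces).
    """
    if prepulses is None:
        prepulses = np.arange(-120.0, -29.0, 10.0)
    peaks, traces = [], []
    for v_pre in prepulses:
        cmd = _step_command(v_pre, [(v_pre, prepulse_ms), (vtest, test_ms)], dt)
        res = integrate(model, cmd, mode="clamp", v0=v_pre)
        i = _ionic_current(res, ion)
        n0 = len(cmd) - int(round(test_ms / dt))
        peaks.append(np.max(np.abs(i[n0:])))
        traces.append(res)
    peaks = np.asarray(peaks)
    if peaks.max() == 0:
        raise ValueError("no test-pulse current over the prepulse grid")
    return np.asarray(prepulses, dtype=float), peaks / peaks.max(), traces


def recovery_protocol(
    model: PatchModel,
    vrec: float = -80.0,
    delays: Sequence[float] | None = None,
    vcond: float = 0.0,
    cond_ms: float = 100.0,
    test_ms: float = 20.0,
    dt: float = 0.01,
    ion: str = "na",
):
    """Recovery from inactivation by paired pulses with increasing delays.

    A long conditioning pulse drives inactivation to its depolarized steady
    state; availability is probed by a test pulse after each delay at the
    recovery potential.  The fraction-vs-delay curve is fitted with a
    single exponential toward its asymptote, yielding tau_rec.

    Returns
    -------
    (delays, fractions, tau_rec) with fractions relative to the
    fully-rested reference peak.
    """
    if delays is None:
        delays = np.geomspace(1.0, 300.0, 10)
    delays = np.asarray(delays, dtype=float)

    # rested reference peak
    cmd_ref = _step_command(vrec, [(vrec, 50.0), (vcond, test_ms)], dt)
    res_ref = integrate(model, cmd_ref, mode="clamp", v0=vrec)
    n0 = len(cmd_ref) - int(round(test_ms / dt))
    ref_peak = np.max(np.abs(_ionic_current(res_ref, ion)[n0:]))
    if ref_peak == 0:
        raise ValueError("reference pulse evoked no current")

    fracs = []
    for d in delays:
        cmd = _step_command(
            vrec, [(vcond, cond_ms), (vrec, d), (vcond, test_ms)], dt
        )
        res = integrate(model, cmd, mode="clamp", v0=vrec)
        nt = len(cmd) - int(round(test_ms / dt))
        fracs.append(np.max(np.abs(_ionic_current(res, ion)[nt:])) / ref_peak)
    fracs = np.asarray(fracs)

    def f(t, f_inf, f0, tau):
        return f_inf - (f_inf - f0) * np.exp(-t / tau)

    p0 = (fracs[-1], fracs[0], np.median(delays))
    popt, _ = curve_fit(
        f, delays, fracs, p0=p0,
        bounds=([0, -0.5, 1e-3], [2.0, 1.0, 1e4]), maxfev=10000,
    )
    tau_rec = float(popt[2])
    return delays, fracs, tau_rec


def ap_clamp(
    model: PatchModel,
    command: Trace,
    ap_times: Sequence[float],
    ion: str = "na",
    window_before: float = 1.0,
):
    """Replay an AP-train command in voltage clamp; per-AP peak amplitudes.

    Peaks are measured per AP in a window from ``window_before`` ms ahead
    of each annotated AP time to the next AP (or trace end) and normalized
    to the first AP's amplitude (first entry exactly 1).

    Returns (normalized_amplitudes, ClampResult).
    """
    ap_times = np.asarray(ap_times, dtype=float)
    if ap_times.size == 0:
        raise ValueError("ap_times is empty")
    t_end = command.t0 + command.duration
    if np.any(ap_times < command.t0) or np.any(ap_times >= t_end):
        raise ValueError("ap_times fall outside the command trace")
    res = integrate(model, command, mode="clamp")
    i = _ionic_current(res, ion)
    edges = np.append(ap_times, t_end)
    amps = np.empty(ap_times.size)
    for k, t_ap in enumerate(ap_times):
        i0 = max(0, int((t_ap - window_before - command.t0) / command.dt))
        i1 = int((edges[k + 1] - command.t0) / command.dt)
        amps[k] = np.max(np.abs(i[i0:i1]))
    if amps[0] == 0:
        raise ValueError("no current during the first AP")
    return amps / amps[0], res


# ---------------------------------------------------------------------------
# current-clamp protocols


def _pulse_stimulus(
    amp: float, pulse_ms: float, total_ms: float, dt: float, onset_ms: float = 5.0
) -> Trace:
    n = int(round(total_ms / dt))
    i = np.zeros(n)
    a, b = int(round(onset_ms / dt)), int(round((onset_ms + pulse_ms) / dt))
    i[a:b] = amp
    return Trace(i, dt, units="pA")


def _has_ap(model, amp, pulse_ms, dt, detect_v=0.0) -> bool:
    stim = _pulse_stimulus(amp, pulse_ms, pulse_ms + 25.0, dt)
    out = integrate(model, stim, mode="free")
    return bool(np.max(out.v.values) > detect_v)


def find_rheobase(
    model: PatchModel,
    pulse_ms: float = 3.0,
    precision: float = 10.0,
    dt: float = 0.025,
    max_amp: float = 20000.0,
    detect_v: float = 0.0,
) -> float:
    """Smallest pulse amplitude (pA) on the precision grid evoking an AP.

    Bisection on the precision grid; equivalent to an exhaustive scan of
    multiples of ``precision`` because AP generation is monotone in the
    pulse amplitude for this model class.  Raises if even ``max_amp`` fails
    to evoke a spike (AP peak above ``detect_v``).
    """
    if not _has_ap(model, max_amp, pulse_ms, dt, detect_v):
        raise RuntimeError(f"no AP evoked at the maximal tested amplitude {max_amp} pA")
    lo, hi = 0, int(math.ceil(max_amp / precision))  # lo: no AP, hi: AP
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _has_ap(model, mid * precision, pulse_ms, dt, detect_v):
            hi = mid
        else:
            lo = mid
    return hi * precision


def simulate_ap_train(
    model: PatchModel,
    freq: float,
    n_aps: int,
    pulse_ms: float = 3.0,
    amp: float | None = None,
    rheobase_factor: float = 1.5,
    dt: float = 0.025,
    tail_ms: float = 20.0,
    detect_v: float = 0.0,
) -> SimResult:
    """Evoke a train of APs with short pulses at ``freq`` Hz.

    ``amp`` defaults to 150% of the model rheobase (determined at 10 pA
    precision).  Pulse onsets are spaced exactly 1000/freq ms apart.  All
    pulses must fire; failures raise with the failed pulse indices.
    """
    period = 1000.0 / freq
    if period <= pulse_ms:
        raise ValueError("inter-pulse interval must exceed the pulse width")
    if amp is None:
        amp = rheobase_factor * find_rheobase(model, pulse_ms, dt=dt)
    onset = 5.0
    total = onset + n_aps * period + tail_ms
    n = int(round(total / dt))
    i = np.zeros(n)
    onsets = onset + period * np.arange(n_aps)
    for t_on in onsets:
        a, b = int(round(t_on / dt)), int(round((t_on + pulse_ms) / dt))
        i[a:b] = amp
    stim = Trace(i, dt, units="pA", meta={"freq_hz": freq, "amp_pa": amp})
    out = integrate(model, stim, mode="free")
    v = out.v.values
    failed = []
    for k, t_on in enumerate(onsets):
        a = int(round(t_on / dt))
        b = min(n, int(round((t_on + period) / dt)))
        if np.max(v[a:b]) <= detect_v:
            failed.append(k)
    if failed:
        raise RuntimeError(f"AP failure at pulse indices {failed}")
    out.v.meta.update(stim.meta)
    return out
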