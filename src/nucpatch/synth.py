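"""Synthetic voltage-clamp cohorts and AP-command waveforms.

Stands in for nucleated-patch recordings: per-cell channel models are
drawn around a species preset with the published inter-cell V1/2 spreads,
run through the voltage-clamp protocol battery, and dressed with the
artifacts a real rig produces — linear leak, biexponential capacitive
transients at step edges (scaling linearly with step size) and Gaussian
recording noise — plus P/-5 scaling sweeps so leak subtraction can be
exercised.  Every dataset carries its generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .gates import KChannelModel, NaChannelModel
from .presets import species_preset
from .simulator import (
    PatchModel,
    simulate_ap_train,
    steady_state_activation_protocol,
    steady_state_inactivation_protocol,
)
from .traces import Trace
from .apshape import detect_threshold

__all__ = [
    "CohortSpec",
    "CellRecording",
    "CohortDataset",
    "synth_vclamp_cohort",
    "synth_ap_command",
    "p_by_n_subtract",
]

#: published cohort SDs of V1/2 (mV) per (species, ion, curve)
VHALF_SD = {
    ("human", "na"): {"act": 4.9, "inact": 7.8},
    ("mouse", "na"): {"act": 4.6, "inact": 6.8},
    ("human", "k"): {"act": 5.9, "inact": 6.0},
    ("mouse", "k"): {"act": 6.0, "inact": 5.3},
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic voltage-clamp cohort.

    ``vhalf_sd_*`` default to the published cohort SDs for the chosen
    species/ion.  ``noise_sd`` is the per-sample Gaussian recording noise
    (pA); ``leak_g`` an uncompensated linear leak (pS um^-2) and
    ``cap_amp`` the capacitive-transient amplitude per mV of step size
    (pA/mV), both removable by P/-5 subtraction.
    """

    n_cells: int = 15
    species: Literal["human", "mouse"] = "human"
    ion: Literal["na", "k"] = "na"
    vhalf_sd_act: float | None = None
    vhalf_sd_inact: float | None = None
    q_sd: float = 0.5
    tau_scale_sd: float = 0.1
    noise_sd: float = 10.0
    leak_g: float = 2.0
    leak_e: float = -90.0
    cap_amp: float = 5.0
    cap_taus: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        for s in (self.vhalf_sd_act, self.vhalf_sd_inact, self.q_sd,
                  self.tau_scale_sd, self.noise_sd):
            if s is not None and s < 0:
                raise ValueError("spread/noise SDs must be >= 0")

    def sd_act(self) -> float:
        if self.vhalf_sd_act is not None:
            return self.vhalf_sd_act
        return VHALF_SD[(self.species, self.ion)]["act"]

    def sd_inact(self) -> float:
        if self.vhalf_sd_inact is not None:
            return self.vhalf_sd_inact
        return VHALF_SD[(self.species, self.ion)]["inact"]


@dataclass
class CellRecording:
    """One synthetic cell: raw protocol traces + P/-5 sweeps + ground truth."""

    cell_id: int
    channel: NaChannelModel | KChannelModel
    activation_v: np.ndarray
    activation_traces: list[Trace]
    activation_p5: list[list[Trace]]
    inactivation_v: np.ndarray
    inactivation_traces: list[Trace]
    inactivation_p5: list[list[Trace]]


@dataclass
class CohortDataset:
    spec: CohortSpec
    cells: list[CellRecording]
    ground_truth: dict


def _perturb_channel(ch, spec: CohortSpec, rng) -> NaChannelModel | KChannelModel:
    dv_a = rng.normal(0.0, spec.sd_act())
    dv_i = rng.normal(0.0, spec.sd_inact())
    dq_a = rng.normal(0.0, spec.q_sd)
    dq_i = rng.normal(0.0, spec.q_sd)
    s_m = float(np.exp(rng.normal(0.0, spec.tau_scale_sd)))
    s_h = float(np.exp(rng.normal(0.0, spec.tau_scale_sd)))

    def scale_rates(kin, s):
        # rates scale inversely with a tau scale factor
        k = list(kin)
        k[0] /= s
        k[1] /= s
        return tuple(k)

    m = ch.m.with_(
        vhalf=ch.m.vhalf + dv_a, q=max(0.5, ch.m.q + dq_a),
        kin=scale_rates(ch.m.kin, s_m),
    )
    if isinstance(ch, NaChannelModel):
        h = ch.h.with_(
            vhalf=ch.h.vhalf + dv_i, q=max(0.5, ch.h.q + dq_i),
            kin=scale_rates(ch.h.kin, s_h),
        )
        return replace(ch, m=m, h=h)
    h1 = ch.h1.with_(
        vhalf=ch.h1.vhalf + dv_i, q=max(0.5, ch.h1.q + dq_i),
        kin=scale_rates(ch.h1.kin, s_h),
    )
    h2 = ch.h2.with_(vhalf=h1.vhalf, q=h1.q)
    return replace(ch, m=m, h1=h1, h2=h2)


def _artifacts(cmd: Trace, spec: CohortSpec, area: float) -> np.ndarray:
    """Linear leak + biexponential capacitive transients for a command."""
    v = cmd.values
    leak = spec.leak_g * area * 1e-3 * (v - spec.leak_e)
    cap = np.zeros_like(v)
    dv = np.diff(v)
    edges = np.nonzero(np.abs(dv) > 1e-9)[0]
    t = np.arange(v.size) * cmd.dt
    for e in edges:
        step = dv[e]
        tt = t[e + 1 :] - t[e + 1]
        tr = spec.cap_amp * step * (
            0.7 * np.exp(-tt / spec.cap_taus[0]) + 0.3 * np.exp(-tt / spec.cap_taus[1])
        )
        cap[e + 1 :] += tr
    return leak + cap


def _dress(
    res_cmd: Trace, clean: np.ndarray, spec: CohortSpec, area: float, rng
) -> tuple[Trace, list[Trace]]:
    """Raw trace (clean + artifacts + noise) and its 5 P/-5 sweeps."""
    raw = clean + _artifacts(res_cmd, spec, area)
    raw = raw + rng.normal(0.0, spec.noise_sd, raw.size)
    main = Trace(raw, res_cmd.dt, units="pA", meta={"raw": True})
    # P/-5 sweeps: command deflection scaled by -1/5 around holding; the rig
    # records them baseline-subtracted, so each sweep is the pure step-locked
    # linear artifact (leak deflection + capacitive transient) plus noise.
    baseline = float(res_cmd.values[0])
    scaled_cmd = Trace(
        baseline + (res_cmd.values - baseline) / -5.0, res_cmd.dt, units="mV"
    )
    hold_cmd = Trace(
        np.full(res_cmd.values.size, baseline), res_cmd.dt, units="mV"
    )
    art = _artifacts(scaled_cmd, spec, area) - _artifacts(hold_cmd, spec, area)
    sweeps = [
        Trace(
            art + rng.normal(0.0, spec.noise_sd, art.size),
            res_cmd.dt, units="pA", meta={"p_over_n": -5},
        )
        for _ in range(5)
    ]
    return main, sweeps


def p_by_n_subtract(main: Trace, sweeps: Sequence[Trace], scale: float = -5.0) -> Trace:
    """P/-5 leak subtraction: remove linear leak/capacitive components.

    The sweeps were recorded with the command deflection scaled by
    1/scale; averaging them and multiplying by ``scale`` reconstructs the
    step-locked linear artifact of the main command, which is then
    subtracted.  The constant holding-level leak offset is not touched
    (it carries no step-locked information and drops out of any peak or
    baseline-referenced measurement).
    """
    avg = np.mean([s.values for s in sweeps], axis=0)
    out = main.copy()
    out.values = main.values - scale * avg
    out.meta["leak_subtracted"] = True
    return out


def synth_vclamp_cohort(spec: CohortSpec, dt: float = 0.02) -> CohortDataset:
    """Generate a cohort of synthetic voltage-clamp recordings.

    Per cell: a perturbed copy of the species preset, steady-state
    activation and inactivation protocols simulated on a clean
    single-channel patch, artifacts and noise added, P/-5 sweeps attached.
    Bit-reproducible from (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    base = species_preset(f"{spec.species}_{spec.ion}")
    cells = []
    truth = {"spec": spec, "cells": {}}
    act_steps = np.arange(-80.0, 41.0, 10.0)
    inact_pre = np.arange(-120.0, -19.0, 10.0)
    for cid in range(spec.n_cells):
        ch = _perturb_channel(base, spec, rng)
        if spec.ion == "na":
            patch = PatchModel(na_channels=(ch,), gleak=0.0)
        else:
            patch = PatchModel(k_channels=(ch,), gleak=0.0)
        area = patch.area

        v_act, _, act_res = steady_state_activation_protocol(
            patch, steps=act_steps, step_ms=30.0 if spec.ion == "na" else 100.0,
            dt=dt, ion=spec.ion,
        )
        act_traces, act_p5 = [], []
        for r in act_res:
            clean = r.i_na if spec.ion == "na" else r.i_k
            main, sweeps = _dress(r.command, clean, spec, area, rng)
            act_traces.append(main)
            act_p5.append(sweeps)

        v_inact, _, inact_res = steady_state_inactivation_protocol(
            patch, prepulses=inact_pre, prepulse_ms=300.0, dt=dt, ion=spec.ion
        )
        inact_traces, inact_p5 = [], []
        for r in inact_res:
            clean = r.i_na if spec.ion == "na" else r.i_k
            main, sweeps = _dress(r.command, clean, spec, area, rng)
            inact_traces.append(main)
            inact_p5.append(sweeps)

        cells.append(
            CellRecording(
                cell_id=cid, channel=ch,
                activation_v=v_act, activation_traces=act_traces,
                activation_p5=act_p5,
                inactivation_v=v_inact, inactivation_traces=inact_traces,
                inactivation_p5=inact_p5,
            )
        )
        gate_i = ch.h if spec.ion == "na" else ch.h1
        truth["cells"][cid] = {
            "vhalf_act": gate_vhalf(ch.m), "q_act": ch.m.q,
            "vhalf_inact": gate_vhalf(gate_i), "q_inact": gate_i.q,
        }
    return CohortDataset(spec=spec, cells=cells, ground_truth=truth)


def gate_vhalf(gate) -> float:
    return float(gate.vhalf)


def synth_ap_command(
    species_like: Literal["human", "mouse"],
    freq: float = 40.0,
    n_aps: int = 200,
    gmax_na: float = 500.0,
    gmax_k: float = 70.0,
    dt: float = 0.025,
) -> tuple[Trace, np.ndarray]:
    """AP-train voltage waveform usable as an AP-clamp command.

    Generated by simulating the corresponding single-species spiking model
    (a synthetic stand-in for an experimentally recorded command).
    Returns ``(voltage_trace, ap_peak_times_ms)``.
    """
    na = species_preset(f"{species_like}_na").with_gmax(gmax_na)
    k = species_preset(f"{species_like}_k").with_gmax(gmax_k)
    model = PatchModel(na_channels=(na,), k_channels=(k,))
    out = simulate_ap_train(model, freq=freq, n_aps=n_aps, dt=dt)
    dets = detect_threshold(out.v)
    peaks = np.array([d.t_peak for d in dets])
    cmd = out.v.copy()
    cmd.meta.update({"species_like": species_like, "freq_hz": freq})
    return cmd, peaks
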