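"""Gating-variable mathematics and conductance laws for Na+ and K+ channel models.

Hodgkin-Huxley style channels in which the steady state of each gating
variable is a Boltzmann function of membrane potential while the time
constant follows a separate voltage-dependent rate scheme.  Decoupling the
steady state from the rates lets steady-state voltage dependence and
transition kinetics be manipulated (and fitted) independently, which is the
point of the whole exercise: human and mouse cortical channels differ in
both, and in different directions.

Conventions
-----------
Voltages are mV, times ms, rates ms^-1, conductance densities pS*um^-2.
Activation gates open with depolarization, inactivation gates close with
depolarization; both steady states are strictly monotone Boltzmann curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GateSpec",
    "NaChannelModel",
    "KChannelModel",
    "ChannelMix",
    "steady_state",
    "time_constant",
    "gate_derivative",
    "na_conductance",
    "k_conductance",
    "mixed_densities",
]

GateKind = Literal["activation", "inactivation"]

#: parameter counts for the rate-based time-constant forms
_N_KIN_ACT = 4
_N_KIN_INACT = 6
_N_KIN_TWO_REGIME = 2


def _linoid(x: np.ndarray | float, q: float):
    """x / (1 - exp(-x/q)) with the removable singularity at x = 0 filled in.

    This is the classic "trap"/linoid rate shape: linear in x for large
    positive x, exponentially suppressed for negative x.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7 * abs(q)
    xs = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):  # exp overflow -> inf -> correct 0 limit
        out = xs / (1.0 - np.exp(-xs / q))
    out = np.where(small, q, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: Boltzmann steady state + voltage-dependent tau.

    Parameters
    ----------
    vhalf : float
        Boltzmann midpoint (mV).
    q : float
        Boltzmann slope factor (mV, > 0).
    kind : {"activation", "inactivation"}
        Direction of the steady-state curve.
    kin : tuple of float
        Time-constant parameters.  Interpretation depends on ``tau_form``:

        ``"rates"`` with 4 parameters ``(ra, rb, tha, qa)`` —
            alpha(V) = ra * linoid(V - tha, qa),
            beta(V)  = rb * linoid(tha - V, qa),
            tau = 1 / (alpha + beta).  Used for activation kinetics.
        ``"rates"`` with 6 parameters ``(rd, rg, thi1, thi2, qd, qg)`` —
            alpha(V) = rd * linoid(V - thi1, qd)   (onset branch),
            beta(V)  = rg * linoid(thi2 - V, qg)   (recovery branch),
            tau = 1 / (alpha + beta).  Used for inactivation kinetics; the
            two half-points allow asymmetric onset/recovery limbs.
        ``"two_regime"`` with 2 parameters ``(tau_onset, tau_recovery)`` —
            tau is constant per regime, selected by whether the gate is
            above (relaxing down, onset) or below (recovering) its steady
            state.  Used for slow K+ inactivation where no voltage
            modulation of tau is resolved.
    """

    vhalf: float
    q: float
    kind: GateKind
    kin: tuple[float, ...]
    tau_form: Literal["rates", "two_regime"] = "rates"

    def __post_init__(self):
        if not self.q > 0:
            raise ValueError(f"Boltzmann slope q must be > 0, got {self.q}")
        if self.kind not in ("activation", "inactivation"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "kin", tuple(float(k) for k in self.kin))
        n = len(self.kin)
        if self.tau_form == "rates" and n not in (_N_KIN_ACT, _N_KIN_INACT):
            raise ValueError(
                f"rate-based tau needs {_N_KIN_ACT} or {_N_KIN_INACT} "
                f"parameters, got {n}"
            )
        if self.tau_form == "two_regime" and n != _N_KIN_TWO_REGIME:
            raise ValueError(f"two-regime tau needs 2 parameters, got {n}")

    def with_(self, **kw) -> "GateSpec":
        return replace(self, **kw)


def steady_state(v, gate: GateSpec):
    """Boltzmann steady state of a gate at membrane potential ``v`` (mV).

    Activation: 1 / (1 + exp((vhalf - V)/q)) — increases with V.
    Inactivation: 1 / (1 + exp((V - vhalf)/q)) — decreases with V.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    if gate.kind == "activation":
        x = (gate.vhalf - v) / gate.q
    else:
        x = (v - gate.vhalf) / gate.q
    out = 1.0 / (1.0 + np.exp(x))
    return float(out) if out.ndim == 0 else out


def time_constant(v, gate: GateSpec, x: float | None = None):
    """Voltage-dependent time constant tau(V) in ms (strictly positive).

    For ``two_regime`` gates the regime depends on the current gate value
    ``x`` relative to its steady state; with ``x`` omitted the onset value
    is returned.
    """
    v = np.asarray(v, dtype=float)
    if gate.tau_form == "two_regime":
        tau_on, tau_rec = gate.kin
        if x is None:
            out = np.full_like(v, tau_on, dtype=float)
        else:
            xinf = steady_state(v, gate)
            out = np.where(np.asarray(x) > xinf, tau_on, tau_rec)
        return float(out) if out.ndim == 0 else out

    if len(gate.kin) == _N_KIN_ACT:
        ra, rb, tha, qa = gate.kin
        alpha = ra * _linoid(v - tha, qa)
        beta = rb * _linoid(tha - v, qa)
    else:
        rd, rg, thi1, thi2, qd, qg = gate.kin
        alpha = rd * _linoid(v - thi1, qd)
        beta = rg * _linoid(thi2 - v, qg)
    out = 1.0 / (np.asarray(alpha) + np.asarray(beta))
    return float(out) if out.ndim == 0 else out


def gate_derivative(x, v, gate: GateSpec):
    """First-order relaxation rate dx/dt = (x_inf(V) - x) / tau(V) (ms^-1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("gate value must lie in [0, 1]")
    xinf = steady_state(v, gate)
    tau = time_constant(v, gate, x=x if gate.tau_form == "two_regime" else None)
    out = (xinf - x) / tau
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NaChannelModel:
    """Transient Na+ channel, conductance g = gmax * m**p * h."""

    gmax: float  # pS um^-2
    m: GateSpec
    h: GateSpec
    p: int = 3
    name: str = "na"

    def __post_init__(self):
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if self.p < 1 or int(self.p) != self.p:
            raise ValueError("activation exponent p must be an integer >= 1")
        if self.m.kind != "activation" or self.h.kind != "inactivation":
            raise ValueError("Na model needs an activation m and inactivation h gate")

    def with_gmax(self, gmax: float) -> "NaChannelModel":
        return replace(self, gmax=gmax)


@dataclass(frozen=True)
class KChannelModel:
    """Delayed-rectifier-like K+ channel with three inactivation fractions.

    Total conductance is the sum of a fast-inactivating fraction (h1), a
    slow-inactivating fraction (h2) and a non-inactivating remainder:

        gk = gmax * m^2 * [frac_inact * ((1-frac_h2)*h1 + frac_h2*h2)
                           + (1 - frac_inact)]

    ``frac_h2`` (default 0.4) is the slow share of the inactivating
    conductance; ``frac_inact`` (default 0.85) is the inactivating share of
    the total, leaving a 15% non-inactivating floor.
    """

    gmax: float
    m: GateSpec
    h1: GateSpec
    h2: GateSpec
    frac_inact: float = 0.85
    frac_h2: float = 0.4
    name: str = "k"

    def __post_init__(self):
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        for f in (self.frac_inact, self.frac_h2):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.m.kind != "activation":
            raise ValueError("K model m gate must be an activation gate")
        if self.h1.kind != "inactivation" or self.h2.kind != "inactivation":
            raise ValueError("K model h1/h2 must be inactivation gates")
        if self.h2.tau_form != "two_regime":
            raise ValueError("slow inactivation gate h2 uses two-regime kinetics")

    def with_gmax(self, gmax: float) -> "KChannelModel":
        return replace(self, gmax=gmax)


def shared_inactivation_k(
    human: KChannelModel, mouse: KChannelModel
) -> tuple[KChannelModel, KChannelModel]:
    """Return the pair with mouse h1/h2 *kinetics* copied onto human values.

    Human and mouse K+ channels share identical inactivation dynamics (time
    constants of inactivation and recovery) while keeping species-specific
    steady-state inactivation curves.  The shared kinetics are taken from
    the ``human`` argument.
    """
    h1 = mouse.h1.with_(kin=human.h1.kin)
    h2 = mouse.h2.with_(kin=human.h2.kin)
    return human, replace(mouse, h1=h1, h2=h2)


def _check_gate_values(*vals):
    for v in vals:
        arr = np.asarray(v)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("gate values must lie in [0, 1]")


def na_conductance(m, h, model: NaChannelModel):
    """g = gmax * m**p * h (pS um^-2)."""
    _check_gate_values(m, h)
    return model.gmax * np.asarray(m) ** model.p * np.asarray(h)


def k_conductance(m, h1, h2, model: KChannelModel):
    """Three-fraction K+ conductance (pS um^-2); see :class:`KChannelModel`."""
    _check_gate_values(m, h1, h2)
    fi, f2 = model.frac_inact, model.frac_h2
    m2 = np.asarray(m) ** 2
    inact = fi * ((1.0 - f2) * np.asarray(h1) + f2 * np.asarray(h2))
    return model.gmax * m2 * (inact + (1.0 - fi))


@dataclass(frozen=True)
class ChannelMix:
    """Total Na+/K+ densities split between human- and mouse-property channels.

    The human fraction scales density linearly:
    g_human = gmax * humanfrac and g_mouse = gmax * (1 - humanfrac) for each
    ion, so the four resulting populations always conserve the totals.
    """

    gmax_na: float
    gmax_k: float
    humanfrac_na: float = 0.5
    humanfrac_k: float = 0.5

    def __post_init__(self):
        if self.gmax_na < 0 or self.gmax_k < 0:
            raise ValueError("total densities must be >= 0")
        for f in (self.humanfrac_na, self.humanfrac_k):
            if not 0.0 <= f <= 1.0:
                raise ValueError("human fractions must lie in [0, 1]")


def mixed_densities(mix: ChannelMix) -> dict[str, float]:
    """Densities of the four channel populations (pS um^-2).

    Returns keys ``na_human``, ``na_mouse``, ``k_human``, ``k_mouse``; their
    sum equals ``gmax_na + gmax_k`` for any fractions.
    """
    return {
        "na_human": mix.gmax_na * mix.humanfrac_na,
        "na_mouse": mix.gmax_na * (1.0 - mix.humanfrac_na),
        "k_human": mix.gmax_k * mix.humanfrac_k,
        "k_mouse": mix.gmax_k * (1.0 - mix.humanfrac_k),
    }
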