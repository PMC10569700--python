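"""Numba-compiled integration kernels for the single-compartment model.

Channel parameters are packed into flat float64 rows so the hot loop stays
in nopython mode:

Na row (16): gmax, p, vhalf_m, q_m, ra, rb, tha, qa,
             vhalf_h, q_h, rd, rg, thi1, thi2, qd, qg
K row (19):  gmax, vhalf_m, q_m, ra, rb, tha, qa,
             vhalf_h, q_h, rd, rg, thi1, thi2, qd, qg,
             tau_h2_on, tau_h2_rec, frac_inact, frac_h2

The integrator uses an exponential (analytic) update for every gate at the
voltage frozen within the step and a backward-Euler update for the membrane
potential, which is linear in V once conductances are fixed.  Both updates
are unconditionally stable.  Gate values are clamped to [0, 1] after each
step to absorb floating-point overshoot.

Unit system: mV, ms, pA, pF, nS; densities pS*um^-2, areas um^2
(conductance nS = density * area * 1e-3; pA = nS * mV; mV/ms = pA/pF).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NA_ROW = 16
K_ROW = 19


@njit(cache=True, inline="always")
def _linoid(x, q):
    if abs(x) < 1e-7 * abs(q):
        return q
    return x / (1.0 - np.exp(-x / q))


@njit(cache=True, inline="always")
def _boltz(v, vhalf, q, sign):
    # sign=+1 activation, -1 inactivation
    return 1.0 / (1.0 + np.exp(sign * (vhalf - v) / q))


@njit(cache=True, inline="always")
def _tau4(v, ra, rb, tha, qa):
    a = ra * _linoid(v - tha, qa)
    b = rb * _linoid(tha - v, qa)
    return 1.0 / (a + b)


@njit(cache=True, inline="always")
def _tau6(v, rd, rg, thi1, thi2, qd, qg):
    a = rd * _linoid(v - thi1, qd)
    b = rg * _linoid(thi2 - v, qg)
    return 1.0 / (a + b)


@njit(cache=True, inline="always")
def _relax(x, xinf, tau, dt):
    y = xinf + (x - xinf) * np.exp(-dt / tau)
    if y < 0.0:
        y = 0.0
    elif y > 1.0:
        y = 1.0
    return y


@njit(cache=True)
def _step_gates(v, na_p, k_p, na_s, k_s, dt):
    for i in range(na_p.shape[0]):
        r = na_p[i]
        minf = _boltz(v, r[2], r[3], 1.0)
        taum = _tau4(v, r[4], r[5], r[6], r[7])
        na_s[i, 0] = _relax(na_s[i, 0], minf, taum, dt)
        hinf = _boltz(v, r[8], r[9], -1.0)
        tauh = _tau6(v, r[10], r[11], r[12], r[13], r[14], r[15])
        na_s[i, 1] = _relax(na_s[i, 1], hinf, tauh, dt)
    for i in range(k_p.shape[0]):
        r = k_p[i]
        minf = _boltz(v, r[1], r[2], 1.0)
        taum = _tau4(v, r[3], r[4], r[5], r[6])
        k_s[i, 0] = _relax(k_s[i, 0], minf, taum, dt)
        hinf = _boltz(v, r[7], r[8], -1.0)
        tauh1 = _tau6(v, r[9], r[10], r[11], r[12], r[13], r[14])
        k_s[i, 1] = _relax(k_s[i, 1], hinf, tauh1, dt)
        # slow gate: constant tau per regime (onset above steady state,
        # recovery below)
        tau2 = r[15] if k_s[i, 2] > hinf else r[16]
        k_s[i, 2] = _relax(k_s[i, 2], hinf, tau2, dt)


@njit(cache=True, inline="always")
def _conductances(na_p, k_p, na_s, k_s, area):
    """Total Na and K conductances in nS given current gate states."""
    g_na = 0.0
    for i in range(na_p.shape[0]):
        r = na_p[i]
        m = na_s[i, 0]
        mp = m
        for _ in range(int(r[1]) - 1):
            mp *= m
        g_na += r[0] * mp * na_s[i, 1]
    g_k = 0.0
    for i in range(k_p.shape[0]):
        r = k_p[i]
        fi = r[17]
        f2 = r[18]
        inact = fi * ((1.0 - f2) * k_s[i, 1] + f2 * k_s[i, 2])
        g_k += r[0] * k_s[i, 0] * k_s[i, 0] * (inact + (1.0 - fi))
    return g_na * area * 1e-3, g_k * area * 1e-3


@njit(cache=True)
def run_free(
    v0,
    na_p,
    k_p,
    na_s,
    k_s,
    area,
    c_pf,
    ena,
    ek,
    g_leak_ns,
    eleak,
    i_inj,
    dt,
):
    """Current-clamp integration.

    Returns (v, h_na) where v[n] is the membrane potential after n steps
    (v[0] = v0) and h_na is the density-weighted mean Na inactivation gate
    (channel availability) at each sample.
    """
    n = i_inj.size
    v_out = np.empty(n)
    h_out = np.empty(n)
    w_tot = 0.0
    for i in range(na_p.shape[0]):
        w_tot += na_p[i, 0]
    if w_tot <= 0.0:
        w_tot = 1.0

    v = v0
    for t in range(n):
        v_out[t] = v
        hw = 0.0
        for i in range(na_p.shape[0]):
            hw += na_p[i, 0] * na_s[i, 1]
        h_out[t] = hw / w_tot

        _step_gates(v, na_p, k_p, na_s, k_s, dt)
        g_na, g_k = _conductances(na_p, k_p, na_s, k_s, area)
        g_sum = g_na + g_k + g_leak_ns
        ge_sum = g_na * ena + g_k * ek + g_leak_ns * eleak
        # backward Euler on C dV/dt = -(g_sum*V - ge_sum) + I
        v = (v + (dt / c_pf) * (ge_sum + i_inj[t])) / (1.0 + (dt / c_pf) * g_sum)
    return v_out, h_out


@njit(cache=True)
def run_clamp(
    vcmd,
    na_p,
    k_p,
    na_s,
    k_s,
    area,
    c_pf,
    ena,
    ek,
    g_leak_ns,
    eleak,
    dt,
):
    """Voltage-clamp integration following the command waveform exactly.

    Returns (i_na, i_k, i_leak, i_cap, na_gates, k_gates); currents in pA
    (positive = outward), gate arrays sampled per step.
    """
    n = vcmd.size
    i_na = np.empty(n)
    i_k = np.empty(n)
    i_leak = np.empty(n)
    i_cap = np.empty(n)
    na_g = np.empty((n, na_p.shape[0] * 2))
    k_g = np.empty((n, k_p.shape[0] * 3))

    for t in range(n):
        v = vcmd[t]
        _step_gates(v, na_p, k_p, na_s, k_s, dt)
        g_na, g_k = _conductances(na_p, k_p, na_s, k_s, area)
        i_na[t] = g_na * (v - ena)
        i_k[t] = g_k * (v - ek)
        i_leak[t] = g_leak_ns * (v - eleak)
        if t + 1 < n:
            i_cap[t] = c_pf * (vcmd[t + 1] - v) / dt
        else:
            i_cap[t] = 0.0
        for i in range(na_p.shape[0]):
            na_g[t, 2 * i] = na_s[i, 0]
            na_g[t, 2 * i + 1] = na_s[i, 1]
        for i in range(k_p.shape[0]):
            k_g[t, 3 * i] = k_s[i, 0]
            k_g[t, 3 * i + 1] = k_s[i, 1]
            k_g[t, 3 * i + 2] = k_s[i, 2]
    return i_na, i_k, i_leak, i_cap, na_g, k_g
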