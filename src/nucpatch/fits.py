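"""Curve fitting for voltage-clamp currents and derived quantities.

Exponential fits to current kinetics (mono-, compound and double
exponential), Boltzmann fits to steady-state curves, conductance-density
conversion and the sodium charge-fraction integral.  All nonlinear fits are
bounded least squares with a small multi-start (3 starts) to dodge local
minima; every result carries an R^2 and the uniform inclusion rule
R^2 > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, sosfiltfilt

from .traces import Trace

__all__ = [
    "ExpFitResult",
    "BoltzmannFitResult",
    "lowpass",
    "fit_inactivation_monoexp",
    "fit_activation_compound",
    "fit_double_exp",
    "fit_boltzmann",
    "conductance_density",
    "na_charge_fractions",
]

R2_INCLUDE = 0.9
_FTOL = 1e-8


@dataclass
class ExpFitResult:
    """Exponential fit to a current trace segment.

    ``a`` amplitude (pA), ``b`` steady state (pA), ``d`` onset delay (ms,
    compound fit only), ``tau_m``/``tau_h`` activation/inactivation time
    constants (ms).  ``included`` applies the R^2 > 0.9 rule; ``flags``
    collects convergence / conditioning warnings.
    """

    a: float
    b: float
    tau_h: float
    r2: float
    tau_m: float = np.nan
    d: float = np.nan
    flags: tuple[str, ...] = ()

    @property
    def included(self) -> bool:
        return bool(self.r2 > R2_INCLUDE) and "nonconverged" not in self.flags


@dataclass
class DoubleExpFitResult:
    a_fast: float
    a_slow: float
    tau_fast: float
    tau_slow: float
    b: float
    r2: float
    flags: tuple[str, ...] = ()

    @property
    def included(self) -> bool:
        return bool(self.r2 > R2_INCLUDE)


@dataclass
class BoltzmannFitResult:
    """Boltzmann fit to a normalized conductance/availability curve."""

    vhalf: float
    q: float
    gmax_norm: float
    r2: float
    kind: Literal["activation", "inactivation"] = "activation"

    def availability_at(self, v) -> float | np.ndarray:
        """Evaluate the fitted curve at voltage(s) ``v`` (mV)."""
        v = np.asarray(v, dtype=float)
        sign = 1.0 if self.kind == "activation" else -1.0
        out = self.gmax_norm / (1.0 + np.exp(sign * (self.vhalf - v) / self.q))
        return float(out) if out.ndim == 0 else out


def lowpass(trace: Trace, cutoff_khz: float, order: int = 4) -> Trace:
    """Zero-phase Butterworth low-pass; cutoff in kHz against fs = 1/dt."""
    fs_khz = 1.0 / trace.dt
    if cutoff_khz >= fs_khz / 2:
        return trace.copy()
    sos = butter(order, cutoff_khz / (fs_khz / 2), output="sos")
    out = trace.copy()
    out.values = sosfiltfilt(sos, trace.values)
    return out


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _multistart(resid, starts, bounds):
    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid, p0, bounds=bounds, ftol=_FTOL, xtol=_FTOL, gtol=_FTOL
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _window(trace: Trace, window) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        t = trace.t - trace.t0
        return t, trace.values
    sub = trace.slice_time(*window)
    return sub.t - sub.t0, sub.values


def fit_inactivation_monoexp(trace: Trace, window=None) -> ExpFitResult:
    """Fit I(t) = a * exp(-t/tau_h) + b over the decay window.

    ``window`` is an absolute (t_start, t_stop) in ms; by default the fit
    starts at the extremum of the trace (current peak) and runs to the end.
    """
    if window is None:
        ipk = int(np.argmax(np.abs(trace.values)))
        window = (trace.t0 + ipk * trace.dt, trace.t0 + trace.duration)
    t, y = _window(trace, window)
    if y.size < 4:
        raise ValueError("decay window too short to fit")

    span = float(np.ptp(y)) or 1.0

    def resid(p):
        a, b, tau = p
        return a * np.exp(-t / tau) + b - y

    t_span = max(t[-1], trace.dt)
    starts = [
        (y[0] - y[-1], y[-1], t_span / 5),
        (y[0] - y[-1], y[-1], t_span / 20),
        ((y[0] - y[-1]) / 2, y[-1], t_span),
    ]
    lb = [-10 * span, min(y.min(), 0) - span, trace.dt / 10]
    ub = [10 * span, y.max() + span, 100 * t_span]
    sol = _multistart(resid, starts, (lb, ub))
    flags: tuple[str, ...] = ()
    if sol is None or not sol.success:
        flags = ("nonconverged",)
    if sol is None:
        return ExpFitResult(np.nan, np.nan, np.nan, -np.inf, flags=flags)
    a, b, tau = sol.x
    r2 = _r2(y, a * np.exp(-t / tau) + b)
    return ExpFitResult(a=a, b=b, tau_h=tau, r2=r2, flags=flags)


def fit_activation_compound(trace: Trace, window=None) -> ExpFitResult:
    """Fit I(t) = [1 - e^(-(t-d)/tau_m)] * [a*e^(-(t-d)/tau_h) + b].

    Captures the rising phase while accounting for early inactivation of
    the current.  The model is evaluated as 0 for t < d.  Flags the result
    ill-conditioned when tau_m >= tau_h at the optimum.
    """
    t, y = _window(trace, window)
    if y.size < 6:
        raise ValueError("window too short for the compound fit")
    span = float(np.max(np.abs(y))) or 1.0
    t_span = max(t[-1], trace.dt)

    def model(p):
        d, tau_m, tau_h, a, b = p
        ts = np.clip(t - d, 0.0, None)
        return (1.0 - np.exp(-ts / tau_m)) * (a * np.exp(-ts / tau_h) + b)

    def resid(p):
        return model(p) - y

    ipk = int(np.argmax(np.abs(y)))
    a0 = y[ipk]
    tpk = max(t[ipk], trace.dt)
    starts = [
        (0.0, tpk / 3, 5 * tpk, a0, 0.0),
        (tpk / 10, tpk / 2, 10 * tpk, a0, 0.0),
        (0.0, tpk, 2 * tpk, a0 * 1.5, 0.0),
    ]
    lb = [0.0, trace.dt / 20, trace.dt / 20, -10 * span, -span]
    ub = [t_span / 2, 10 * t_span, 100 * t_span, 10 * span, span]
    sol = _multistart(resid, starts, (lb, ub))
    flags: tuple[str, ...] = ()
    if sol is None or not sol.success:
        flags += ("nonconverged",)
    if sol is None:
        return ExpFitResult(np.nan, np.nan, np.nan, -np.inf, flags=flags)
    d, tau_m, tau_h, a, b = sol.x
    if tau_m >= tau_h:
        flags += ("ill_conditioned",)
    r2 = _r2(y, model(sol.x))
    return ExpFitResult(a=a, b=b, d=d, tau_m=tau_m, tau_h=tau_h, r2=r2, flags=flags)


def fit_double_exp(trace: Trace, window=None) -> DoubleExpFitResult:
    """Fit I(t) = a_f*e^(-t/tau_f) + a_s*e^(-t/tau_s) + b with tau_f < tau_s.

    Ordering is enforced by sorting the two components.  Near-degenerate
    optima (tau_f ~ tau_s) are collapsed to the monoexponential fit and
    flagged.
    """
    if window is None:
        ipk = int(np.argmax(np.abs(trace.values)))
        window = (trace.t0 + ipk * trace.dt, trace.t0 + trace.duration)
    t, y = _window(trace, window)
    if y.size < 6:
        raise ValueError("decay window too short for a double exponential")
    span = float(np.ptp(y)) or 1.0
    t_span = max(t[-1], trace.dt)

    def model(p):
        af, as_, tf, ts_, b = p
        return af * np.exp(-t / tf) + as_ * np.exp(-t / ts_) + b

    def resid(p):
        return model(p) - y

    amp = y[0] - y[-1]
    starts = [
        (amp * 0.6, amp * 0.4, t_span / 20, t_span / 2, y[-1]),
        (amp * 0.9, amp * 0.1, t_span / 50, t_span, y[-1]),
        (amp * 0.3, amp * 0.7, t_span / 10, t_span / 3, y[-1]),
    ]
    lb = [-10 * span, -10 * span, trace.dt / 10, trace.dt / 10, y.min() - span]
    ub = [10 * span, 10 * span, 10 * t_span, 100 * t_span, y.max() + span]
    sol = _multistart(resid, starts, (lb, ub))
    if sol is None:
        return DoubleExpFitResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, -np.inf, ("nonconverged",)
        )
    af, as_, tf, ts_, b = sol.x
    if tf > ts_:
        af, as_, tf, ts_ = as_, af, ts_, tf
    flags: tuple[str, ...] = ()
    if not sol.success:
        flags += ("nonconverged",)
    if ts_ > 0 and abs(ts_ - tf) / ts_ < 0.05:
        mono = fit_inactivation_monoexp(trace, window)
        return DoubleExpFitResult(
            mono.a, 0.0, mono.tau_h, mono.tau_h, mono.b, mono.r2,
            flags + ("degenerate_monoexp",),
        )
    r2 = _r2(y, af * np.exp(-t / tf) + as_ * np.exp(-t / ts_) + b)
    return DoubleExpFitResult(af, as_, tf, ts_, b, r2, flags)


def fit_boltzmann(
    v, g, kind: Literal["activation", "inactivation"] = "activation"
) -> BoltzmannFitResult:
    """Least-squares Boltzmann fit to a (V, G/Gmax) curve.

    Requires at least 4 points and a real transition inside the voltage
    range (the fitted midpoint must not sit on the grid boundary while the
    curve is essentially flat).
    """
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 points spanning the transition")
    if np.ptp(g) < 1e-3:
        raise ValueError("no transition within the voltage range")
    sign = 1.0 if kind == "activation" else -1.0

    def model(p):
        vh, q, gm = p
        return gm / (1.0 + np.exp(sign * (vh - v) / q))

    def resid(p):
        return model(p) - g

    vh0 = float(v[np.argmin(np.abs(g - 0.5 * g.max()))])
    starts = [(vh0, 5.0, g.max()), (vh0, 10.0, g.max()), (np.median(v), 7.0, 1.0)]
    lb = [v.min() - 50.0, 0.1, 1e-3]
    ub = [v.max() + 50.0, 100.0, 2.0]
    sol = _multistart(resid, starts, (lb, ub))
    if sol is None:
        raise RuntimeError("Boltzmann fit failed to converge")
    vh, q, gm = sol.x
    return BoltzmannFitResult(vh, q, gm, _r2(g, model(sol.x)), kind)


def conductance_density(gmax_ns: float, diameter: float) -> float:
    """Convert a fitted maximal conductance (nS) to a density (pS um^-2).

    Uses the spherical-compartment surface convention area = pi * d^2, the
    same convention as :class:`~nucpatch.simulator.PatchModel`.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return gmax_ns * 1e3 / (np.pi * diameter**2)


def na_charge_fractions(current: Trace, ap_peak_t: float) -> float:
    """Fraction of total Na+ charge transferred after the AP peak.

    ``current`` is the isolated Na+ current during a single AP;
    ``ap_peak_t`` the AP peak time (ms, absolute).  Returns
    integral(|I|, t > peak) / integral(|I|) by trapezoidal integration.
    """
    t = current.t
    y = np.abs(current.values)
    total = float(np.trapezoid(y, t))
    if total == 0:
        raise ValueError("zero total charge in the current trace")
    after = t >= ap_peak_t
    if not np.any(after):
        return 0.0
    # split the trapezoid containing the peak time exactly
    y_after = np.where(after, y, 0.0)
    i0 = int(np.argmax(after))
    if i0 > 0:
        # linear interpolation of |I| at ap_peak_t
        f = (ap_peak_t - t[i0 - 1]) / (t[i0] - t[i0 - 1])
        y_at = y[i0 - 1] + f * (y[i0] - y[i0 - 1])
        after_charge = float(np.trapezoid(y[after], t[after]))
        after_charge += 0.5 * (y_at + y[i0]) * (t[i0] - ap_peak_t)
    else:
        after_charge = float(np.trapezoid(y_after, t))
    return after_charge / total
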