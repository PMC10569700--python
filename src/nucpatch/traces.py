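"""Uniformly sampled time-series container used across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A uniformly sampled voltage (mV) or current (pA) time series.

    Attributes
    ----------
    values : ndarray
        Sample values.
    dt : float
        Sampling interval in ms (> 0).
    t0 : float
        Time of the first sample in ms.
    units : str
        Physical units of ``values`` ("mV", "pA", ...). Mandatory metadata.
    meta : dict
        Free-form metadata (species, protocol, "raw" flag, ...).
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    units: str = "mV"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not self.dt > 0:
            raise ValueError("Trace dt must be > 0")
        if not self.units:
            raise ValueError("Trace requires explicit units")

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def __len__(self) -> int:
        return self.values.size

    def slice_time(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace covering [t_start, t_stop) in absolute time (ms)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt)))
        i1 = min(len(self), int(np.ceil((t_stop - self.t0) / self.dt)))
        return Trace(
            self.values[i0:i1].copy(),
            self.dt,
            t0=self.t0 + i0 * self.dt,
            units=self.units,
            meta=dict(self.meta),
        )

    def copy(self) -> "Trace":
        return Trace(self.values.copy(), self.dt, self.t0, self.units, dict(self.meta))
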