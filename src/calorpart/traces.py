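"""Uniform-grid signal traces.

Everything the chamber records — gas fractions, outflow, force-sensor
voltage, cumulative feed dispensed, temperature, pressure, humidity —
is a :class:`SignalTrace`: values on a strictly uniform grid (10-s ticks
by default), timestamped in seconds from midnight.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import TICK_S

__all__ = ["SignalTrace", "full_day_grid"]


@dataclass
class SignalTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Timestamp of the first sample, seconds from midnight.
    dt : float
        Grid resolution in seconds (default 10 s).
    values : ndarray
        Sample values.  Units depend on the signal (fraction for gas
        concentrations, mV for force sensors, g for cumulative feed,
        L/h for flows).
    """

    t0: float
    dt: float
    values: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1:
            raise ValueError("SignalTrace values must be 1-D")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from midnight."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration_h(self) -> float:
        """Span covered by the trace (each sample owns one tick), hours."""
        return self.n * self.dt / 3600.0

    # -- calculus -------------------------------------------------------
    def integral(self) -> float:
        """Integral of the signal over the trace, in value-units x hours.

        Samples are treated as constant over their own tick, which is the
        convention used by the chamber simulator.
        """
        return float(np.nansum(self.values) * self.dt / 3600.0)

    def with_values(self, values: np.ndarray, **flags) -> "SignalTrace":
        out = replace(self, values=np.asarray(values, dtype=float))
        out.flags = {**self.flags, **flags}
        return out

    def same_grid(self, other: "SignalTrace", atol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.t0 - other.t0) <= atol
            and abs(self.dt - other.dt) <= atol
        )

    # -- I/O ------------------------------------------------------------
    def to_series(self, name: str = "value") -> pd.Series:
        return pd.Series(self.values, index=self.times, name=name)


def full_day_grid(dt: float = TICK_S) -> np.ndarray:
    """Timestamps (s from midnight) of a full-day uniform grid."""
    n = int(round(86400.0 / dt))
    return dt * np.arange(n)
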