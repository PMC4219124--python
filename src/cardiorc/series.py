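"""Uniformly sampled response traces (heart rate, oxygen uptake, or capacitor voltage).

A :class:`ResponseSeries` is the package's common currency: a strictly
increasing time grid in seconds paired with sample values in whatever unit
the signal carries (bpm, ml/min, or volts in the circuit analogy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SeriesError

__all__ = ["ResponseSeries"]


@dataclass(frozen=True)
class ResponseSeries:
    """A sampled physiological or voltage trace.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing.
    values : array-like of float
        Sample values, same length as ``times``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise SeriesError("times and values must be one-dimensional")
        if t.size != v.size:
            raise SeriesError(f"length mismatch: {t.size} times vs {v.size} values")
        if t.size == 0:
            raise SeriesError("empty series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise SeriesError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def slice(self, t_start: float, t_stop: float) -> "ResponseSeries":
        """Sub-series with times in the half-open window [t_start, t_stop)."""
        mask = (self.times >= t_start) & (self.times < t_stop)
        if not mask.any():
            raise SeriesError(f"no samples in [{t_start}, {t_stop})")
        return ResponseSeries(self.times[mask], self.values[mask])

    def value_at(self, t: float) -> float:
        """Linearly interpolated value at time ``t`` (must lie inside the grid)."""
        if t < self.times[0] or t > self.times[-1]:
            raise SeriesError(f"t={t} outside series range")
        return float(np.interp(t, self.times, self.values))

    def resample(self, times: np.ndarray) -> "ResponseSeries":
        """Linear interpolation onto a new grid (must lie inside the span)."""
        times = np.asarray(times, dtype=float)
        if times[0] < self.times[0] or times[-1] > self.times[-1]:
            raise SeriesError("target grid extends beyond the series span")
        return ResponseSeries(times, np.interp(times, self.times, self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})
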