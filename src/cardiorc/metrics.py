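"""Verification metrics: RMSE and correlation between measured and modelled traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SeriesError
from .series import ResponseSeries

__all__ = ["PairedSeries", "rmse", "correlation", "pair_series"]


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned sample vectors: measured data and model output."""

    measured: np.ndarray
    modeled: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.measured, dtype=float)
        y = np.asarray(self.modeled, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise SeriesError("paired series must be one-dimensional")
        if x.size != y.size:
            raise SeriesError(f"length mismatch: {x.size} vs {y.size}")
        if x.size < 1:
            raise SeriesError("paired series must be non-empty")
        object.__setattr__(self, "measured", x)
        object.__setattr__(self, "modeled", y)

    @property
    def n(self) -> int:
        return self.measured.size


def pair_series(measured: ResponseSeries, modeled: ResponseSeries) -> PairedSeries:
    """Align a model trace onto the measured time base.

    The modeled series is linearly interpolated onto the measured sample
    times restricted to the overlap of the two spans (an inner join in
    time).
    """
    lo = max(measured.times[0], modeled.times[0])
    hi = min(measured.times[-1], modeled.times[-1])
    if lo > hi:
        raise SeriesError("series do not overlap in time")
    mask = (measured.times >= lo) & (measured.times <= hi)
    t = measured.times[mask]
    return PairedSeries(
        measured.values[mask], np.interp(t, modeled.times, modeled.values)
    )


def rmse(pair: PairedSeries) -> float:
    """Root-mean-square error between the two series, in response units."""
    d = pair.measured - pair.modeled
    return float(np.sqrt(np.mean(d * d)))


def correlation(pair: PairedSeries) -> float:
    """Pearson correlation of the two series, dimensionless in [-1, 1]."""
    if pair.n < 2:
        raise SeriesError("correlation needs at least 2 samples")
    if np.ptp(pair.measured) == 0 or np.ptp(pair.modeled) == 0:
        raise SeriesError("correlation undefined for a constant series")
    return float(stats.pearsonr(pair.measured, pair.modeled).statistic)
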