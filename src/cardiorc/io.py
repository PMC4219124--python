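"""CSV readers/writers for time series and simulation traces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import CircuitParams, Mode, SimulationResult
from .errors import SeriesError
from .series import ResponseSeries

__all__ = ["read_series", "write_series", "write_trace", "read_trace"]

# 12+ significant digits so a write -> read round trip is lossless for
# practical purposes.
_FLOAT_FMT = "%.15g"


def read_series(path: str | Path, column: str = "value") -> ResponseSeries:
    """Read a two-column CSV (``time_s,<column>`` with header) as a series.

    Raises :class:`SeriesError` naming the offending line for malformed
    rows, and for a non-monotone time base.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise SeriesError(f"{path}: cannot parse CSV: {exc}") from exc
    if "time_s" not in df.columns or column not in df.columns:
        raise SeriesError(f"{path}: header must contain 'time_s' and '{column}'")
    t = pd.to_numeric(df["time_s"], errors="coerce")
    v = pd.to_numeric(df[column], errors="coerce")
    bad = np.nonzero(t.isna().to_numpy() | v.isna().to_numpy())[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise SeriesError(f"{path}: malformed row at line {int(bad[0]) + 2}")
    times = t.to_numpy(dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        i = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise SeriesError(f"{path}: time not strictly increasing at line {i + 3}")
    return ResponseSeries(times, v.to_numpy(dtype=float))


def write_series(series: ResponseSeries, path: str | Path) -> None:
    """Write a series as ``time_s,value`` CSV (15 significant digits)."""
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trace(result: SimulationResult, path: str | Path) -> None:
    """Write a simulation result as ``time_s,v_c1,v_c2,mode,output`` CSV."""
    df = pd.DataFrame(
        {
            "time_s": result.times,
            "v_c1": result.v_c1,
            "v_c2": result.v_c2,
            "mode": [m.value for m in result.mode],
            "output": result.output,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path: str | Path, params: CircuitParams, baseline: float = 0.0) -> SimulationResult:
    """Read a trace CSV written by :func:`write_trace` back into a result.

    The component values are not stored in the CSV, so the matching
    ``params`` must be supplied (they are needed to recompute energy areas).
    """
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"time_s", "v_c1", "v_c2", "mode"}
    if not needed.issubset(df.columns):
        raise SeriesError(f"{path}: trace needs columns {sorted(needed)}")
    mode_strs = df["mode"].to_numpy(dtype=str)
    modes = np.array([Mode(m) for m in mode_strs], dtype=object)
    # the warm-up idles in recovery mode, so t2 is the first recovery sample
    # after the first onset
    t_rec = None
    rec = np.nonzero(mode_strs == Mode.RECOVERY.value)[0]
    onset = np.nonzero(mode_strs == Mode.ONSET.value)[0]
    if rec.size and onset.size:
        after = rec[rec > onset[0]]
        if after.size:
            t_rec = float(df["time_s"].iloc[after[0]])
    return SimulationResult(
        times=df["time_s"].to_numpy(dtype=float),
        v_c1=df["v_c1"].to_numpy(dtype=float),
        v_c2=df["v_c2"].to_numpy(dtype=float),
        mode=modes,
        baseline=baseline,
        params=params,
        t_recovery=t_rec,
    )
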