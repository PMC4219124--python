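"""First-order step-response simulation and identification.

At moderate intensity the heart-rate and oxygen-uptake responses to a step
change in treadmill speed are well approximated by a first-order process

    y(t) = baseline + K * du * (1 - exp(-t / T)),   t >= 0,

where ``K`` is the steady-state gain (response units per km/h of speed
step ``du``) and ``T`` the time constant in seconds.  Onset and offset of
exercise have distinct (K, T) pairs — the offset gain is smaller and the
offset time constant larger — which is what the switching-circuit model in
:mod:`cardiorc.circuit` is built to accommodate.

Identification is nonlinear least squares on the closed form; offset
(recovery) windows are fitted as free-asymptote exponential decays
``y(t) = c + A * exp(-t / T)`` with ``K = A / du``, so the reported offset
gain is a positive magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, SeriesError
from .protocols import ExerciseProtocol, SegmentRole
from .series import ResponseSeries

__all__ = [
    "FirstOrderParams",
    "StepSegment",
    "FitResult",
    "PopulationSummary",
    "simulate_first_order",
    "fit_first_order",
    "fit_exponential_decay",
    "identify_onset_offset",
    "summarize_population",
]

# T is bounded to a physiologically plausible band; cardio-respiratory
# kinetics in untrained adults sit well inside (1, 600) s.
_T_BOUNDS = (1.0, 600.0)


@dataclass(frozen=True)
class FirstOrderParams:
    """Steady-state gain K (units per km/h) and time constant T (s)."""

    K: float
    T: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.K):
            raise ValueError("K must be finite")
        if not (self.T > 0 and np.isfinite(self.T)):
            raise ValueError(f"T must be a positive finite number, got {self.T}")


@dataclass(frozen=True)
class StepSegment:
    """A uniformly sampled window containing one speed step.

    Times are in seconds on a uniform grid; ``step_time`` marks the step
    instant (samples at ``t < step_time`` are pre-step), ``step_amplitude``
    is the speed change in km/h and ``baseline`` the pre-step response level.
    """

    times: np.ndarray
    values: np.ndarray
    step_time: float
    step_amplitude: float
    baseline: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise SeriesError("times/values length mismatch")
        if t.size < 2:
            raise SeriesError("step segment needs at least 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise SeriesError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SeriesError("times must be uniformly spaced")
        if not (t[0] <= self.step_time <= t[-1]):
            raise SeriesError("step_time outside the sampled window")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FitResult:
    """Identified parameters plus goodness-of-fit diagnostics."""

    params: FirstOrderParams
    rmse: float
    n: int
    asymptote: float | None = None  # free asymptote of a decay fit, if any


@dataclass(frozen=True)
class PopulationSummary:
    """Mean and sample STD of the four kinetic coefficients over a cohort."""

    t_on_mean: float
    t_on_sd: float
    k_on_mean: float
    k_on_sd: float
    t_off_mean: float
    t_off_sd: float
    k_off_mean: float
    k_off_sd: float

    def __post_init__(self) -> None:
        for name in ("t_on_mean", "k_on_mean", "t_off_mean", "k_off_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("t_on_sd", "k_on_sd", "t_off_sd", "k_off_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def onset_means(self) -> FirstOrderParams:
        return FirstOrderParams(K=self.k_on_mean, T=self.t_on_mean)

    @property
    def offset_means(self) -> FirstOrderParams:
        return FirstOrderParams(K=self.k_off_mean, T=self.t_off_mean)


def simulate_first_order(
    params: FirstOrderParams,
    step_amplitude: float,
    baseline: float,
    times: np.ndarray,
) -> ResponseSeries:
    """Closed-form saturating step response on the given grid.

    ``times`` are measured from the step instant (t = 0 is the step);
    negative times return the baseline.
    """
    t = np.asarray(times, dtype=float)
    rise = np.where(t >= 0, 1.0 - np.exp(-np.maximum(t, 0.0) / params.T), 0.0)
    return ResponseSeries(t, baseline + params.K * step_amplitude * rise)


def _check_fittable(segment: StepSegment) -> np.ndarray:
    """Post-step sample mask plus degenerate-input checks."""
    if segment.step_amplitude == 0:
        raise FitError("step amplitude is zero; gain is not identifiable")
    post = segment.times >= segment.step_time
    if post.sum() < 10:
        raise FitError(f"need >= 10 post-step samples, got {int(post.sum())}")
    if np.ptp(segment.values[post]) == 0:
        raise FitError("flat signal: response has zero variance")
    return post


def _t0_guess(t: np.ndarray, y: np.ndarray, y_start: float, y_end: float) -> float:
    """Time at which the response has covered 63.2% of its excursion."""
    target = y_start + 0.632 * (y_end - y_start)
    if y_end >= y_start:
        idx = np.nonzero(y >= target)[0]
    else:
        idx = np.nonzero(y <= target)[0]
    t0 = t[idx[0]] if idx.size else 0.3 * (t[-1] - t[0])
    return float(np.clip(t0, _T_BOUNDS[0] * 1.05, _T_BOUNDS[1] * 0.95))


def fit_first_order(segment: StepSegment) -> FitResult:
    """Identify (K, T) of a baseline-anchored first-order rise.

    Bounded nonlinear least squares on
    ``y = baseline + K * du * (1 - exp(-t'/T))`` with ``t'`` measured from
    the step instant.  On noise-free first-order input the generating
    parameters are recovered to ~1e-6 relative.
    """
    post = _check_fittable(segment)
    t = segment.times[post] - segment.step_time
    y = segment.values[post]
    du = segment.step_amplitude
    b = segment.baseline

    k0 = (y[-1] - b) / du
    if k0 == 0:
        k0 = (np.mean(y) - b) / du or 1.0
    t0 = _t0_guess(t, y, b, y[-1])

    def resid(p: np.ndarray) -> np.ndarray:
        K, T = p
        return b + K * du * (1.0 - np.exp(-t / T)) - y

    sol = least_squares(
        resid,
        x0=[k0, t0],
        bounds=([-np.inf, _T_BOUNDS[0]], [np.inf, _T_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"least squares did not converge: {sol.message}")
    K, T = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(FirstOrderParams(K=float(K), T=float(T)), rmse=rmse, n=int(t.size))


def fit_exponential_decay(segment: StepSegment) -> FitResult:
    """Identify an offset window as a free-asymptote exponential decay.

    Fits ``y = c + A * exp(-t'/T)`` and reports the gain magnitude
    ``K = A / |du|``; the asymptote ``c`` is returned in the result so the
    caller can compare it with the pre-exercise baseline.
    """
    post = _check_fittable(segment)
    t = segment.times[post] - segment.step_time
    y = segment.values[post]
    du = abs(segment.step_amplitude)

    c0 = y[-1]
    a0 = y[0] - y[-1]
    if a0 == 0:
        a0 = np.ptp(y) or 1.0
    t0 = _t0_guess(t, y, y[0], y[-1])

    def resid(p: np.ndarray) -> np.ndarray:
        c, A, T = p
        return c + A * np.exp(-t / T) - y

    sol = least_squares(
        resid,
        x0=[c0, a0, t0],
        bounds=([-np.inf, -np.inf, _T_BOUNDS[0]], [np.inf, np.inf, _T_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"least squares did not converge: {sol.message}")
    c, A, T = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(
        FirstOrderParams(K=float(abs(A) / du), T=float(T)),
        rmse=rmse,
        n=int(t.size),
        asymptote=float(c),
    )


def identify_onset_offset(
    series: ResponseSeries,
    protocol: ExerciseProtocol,
) -> tuple[FirstOrderParams, FirstOrderParams]:
    """Fit onset and offset kinetics of a trace recorded under ``protocol``.

    The series is sliced at the protocol's first onset switch and the
    following offset switch.  The onset slice is fitted baseline-anchored
    (baseline = value at the slice start); the offset slice as a
    free-asymptote decay.  Returns ``(onset, offset)`` parameter pairs.
    """
    windows = protocol.segment_windows()
    onset_idx = next(
        (i for i, (_, _, s) in enumerate(windows) if s.role is SegmentRole.ONSET), None
    )
    if onset_idx is None:
        raise FitError("protocol has no onset segment")
    off_idx = next(
        (
            i
            for i, (_, _, s) in enumerate(windows)
            if i > onset_idx and s.role in (SegmentRole.OFFSET, SegmentRole.COOLDOWN)
        ),
        None,
    )
    if off_idx is None:
        raise FitError("protocol has no offset segment after the onset")

    on_start, on_end, on_seg = windows[onset_idx]
    off_start, off_end, off_seg = windows[off_idx]
    if series.times[-1] < off_start:
        raise FitError("series does not cover the offset segment")
    prev_speed = windows[onset_idx - 1][2].speed if onset_idx else on_seg.speed

    on = series.slice(on_start, on_end)
    onset_fit = fit_first_order(
        StepSegment(
            times=on.times - on_start,
            values=on.values,
            step_time=0.0,
            step_amplitude=on_seg.speed - prev_speed,
            baseline=float(on.values[0]),
        )
    )

    off_stop = min(off_end, float(series.times[-1]) + 1e-9)
    off = series.slice(off_start, off_stop)
    offset_fit = fit_exponential_decay(
        StepSegment(
            times=off.times - off_start,
            values=off.values,
            step_time=0.0,
            step_amplitude=on_seg.speed - off_seg.speed,
            baseline=float(off.values[0]),
        )
    )
    return onset_fit.params, offset_fit.params


def summarize_population(
    per_subject: Sequence[tuple[FirstOrderParams, FirstOrderParams]],
) -> PopulationSummary:
    """Mean and sample STD (n−1 denominator) of per-subject (onset, offset) fits."""
    if len(per_subject) < 2:
        raise ValueError("population summary needs at least 2 subjects")
    t_on = np.array([on.T for on, _ in per_subject])
    k_on = np.array([on.K for on, _ in per_subject])
    t_off = np.array([off.T for _, off in per_subject])
    k_off = np.array([off.K for _, off in per_subject])
    return PopulationSummary(
        t_on_mean=float(t_on.mean()),
        t_on_sd=float(t_on.std(ddof=1)),
        k_on_mean=float(k_on.mean()),
        k_on_sd=float(k_on.std(ddof=1)),
        t_off_mean=float(t_off.mean()),
        t_off_sd=float(t_off.std(ddof=1)),
        k_off_mean=float(k_off.mean()),
        k_off_sd=float(k_off.std(ddof=1)),
    )
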