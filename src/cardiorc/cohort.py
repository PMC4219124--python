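"""Synthetic cohort generator.

Emulates the statistical structure of a treadmill study in which every
subject's heart-rate and oxygen-uptake step responses are first-order with
subject-specific coefficients drawn from a population distribution, each
exercise is repeated twice, and the recorded traces are filtered,
interpolated onto a common 1 Hz grid, and averaged — first across a
subject's trials, then across subjects into an ensemble mean with a ±1 STD
band.

Per-subject coefficients are drawn independently from normals with the
population mean/STD, truncated to positive values and resampled until the
empirically observed asymmetry holds (T_off > T_on and K_off < K_on).
Measurement noise is additive i.i.d. Gaussian on every sample; "filtering"
is a centered moving average applied after trial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .first_order import FirstOrderParams, PopulationSummary
from .protocols import ExerciseProtocol
from .reference import (
    DEFAULT_BASELINE_HR,
    DEFAULT_BASELINE_VO2,
    HR_POPULATION,
    VO2_POPULATION,
)
from .series import ResponseSeries

__all__ = [
    "CohortSpec",
    "CohortResult",
    "CohortStudy",
    "sample_subject",
    "generate_trial",
    "build_cohort",
]

_MAX_RESAMPLE = 10_000


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic cohort.

    Defaults mirror the reference study: 20 subjects, 2 trials each
    (40 trials), 1 Hz sampling, noise SD of 2 bpm for HR and 60 ml/min for
    VO2, and a 5-sample centered moving-average filter.
    """

    n_subjects: int = 20
    hr_population: PopulationSummary = field(default_factory=lambda: HR_POPULATION)
    vo2_population: PopulationSummary = field(default_factory=lambda: VO2_POPULATION)
    baseline_hr: float = DEFAULT_BASELINE_HR
    baseline_vo2: float = DEFAULT_BASELINE_VO2
    noise_sd_hr: float = 2.0
    noise_sd_vo2: float = 60.0
    trials_per_subject: int = 2
    seed: int = 0
    smoothing_window: int = 5
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if self.noise_sd_hr < 0 or self.noise_sd_vo2 < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass(frozen=True)
class CohortResult:
    """One signal's cohort output on a common grid."""

    subjects: tuple[ResponseSeries, ...]  # trial-averaged, filtered traces
    subject_params: tuple[tuple[FirstOrderParams, FirstOrderParams], ...]
    ensemble_mean: ResponseSeries
    ensemble_sd: ResponseSeries

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.ensemble_mean.times, "mean": self.ensemble_mean.values,
             "sd": self.ensemble_sd.values}
        return pd.DataFrame(d)


@dataclass(frozen=True)
class CohortStudy:
    """Both signals of a synthetic study."""

    hr: CohortResult
    vo2: CohortResult
    spec: CohortSpec


def sample_subject(
    population: PopulationSummary, rng: np.random.Generator
) -> tuple[FirstOrderParams, FirstOrderParams]:
    """Draw one subject's (onset, offset) coefficients.

    Independent normal draws per coefficient, truncated to positive and
    resampled jointly until T_off > T_on and K_off < K_on.
    """

    def draw(mean: float, sd: float) -> float:
        for _ in range(_MAX_RESAMPLE):
            x = rng.normal(mean, sd)
            if x > 0:
                return float(x)
        raise RuntimeError("positive truncation failed; check population SDs")

    for _ in range(_MAX_RESAMPLE):
        t_on = draw(population.t_on_mean, population.t_on_sd)
        k_on = draw(population.k_on_mean, population.k_on_sd)
        t_off = draw(population.t_off_mean, population.t_off_sd)
        k_off = draw(population.k_off_mean, population.k_off_sd)
        if t_off > t_on and k_off < k_on:
            return (
                FirstOrderParams(K=k_on, T=t_on),
                FirstOrderParams(K=k_off, T=t_off),
            )
        if population.t_on_sd == 0 and population.t_off_sd == 0:
            # degenerate means violating the regime cannot be resampled away
            return (
                FirstOrderParams(K=k_on, T=t_on),
                FirstOrderParams(K=k_off, T=t_off),
            )
    raise RuntimeError("could not draw a subject in the T_off>T_on, K_off<K_on regime")


def _noise_free_trace(
    onset: FirstOrderParams,
    offset: FirstOrderParams,
    protocol: ExerciseProtocol,
    baseline: float,
    dt: float,
) -> ResponseSeries:
    """Piecewise first-order composite over the protocol, continuous at switches.

    At each speed change the response re-targets from its current value:
    an upward step du aims at value + K_on·du with time constant T_on, a
    downward step at value − K_off·|du| with T_off; an unchanged speed
    keeps the previous dynamics running.
    """
    n = int(np.floor(protocol.total_duration / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    values = np.empty(n)

    target, tau = baseline, None
    prev_speed = protocol.segments[0].speed
    y_at = baseline
    for start, end, seg in protocol.segment_windows():
        du = seg.speed - prev_speed
        if du > 0:
            target, tau = y_at + onset.K * du, onset.T
        elif du < 0:
            target, tau = y_at - offset.K * (-du), offset.T
        # du == 0: keep the running (target, tau)
        idx = (times >= start - 1e-9) & (times < end - 1e-9)
        t_rel = times[idx] - start
        if tau is None:
            values[idx] = y_at
            y_end = y_at
        else:
            values[idx] = target + (y_at - target) * np.exp(-t_rel / tau)
            y_end = target + (y_at - target) * np.exp(-(end - start) / tau)
        y_at = float(y_end)
        prev_speed = seg.speed
    if times[-1] >= protocol.total_duration - 1e-9:
        values[-1] = y_at  # final grid point, left-limit at total_duration
    return ResponseSeries(times, values)


def generate_trial(
    onset: FirstOrderParams,
    offset: FirstOrderParams,
    protocol: ExerciseProtocol,
    baseline: float,
    noise_sd: float,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> ResponseSeries:
    """One recorded trial: the subject's composite response plus i.i.d. noise."""
    clean = _noise_free_trace(onset, offset, protocol, baseline, dt)
    noise = rng.normal(0.0, noise_sd, size=len(clean)) if noise_sd > 0 else 0.0
    return ResponseSeries(clean.times, clean.values + noise)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the edges use the available samples only."""
    if window == 1:
        return values
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _one_signal(
    population: PopulationSummary,
    baseline: float,
    noise_sd: float,
    spec: CohortSpec,
    protocol: ExerciseProtocol,
    rng: np.random.Generator,
) -> CohortResult:
    subjects: list[ResponseSeries] = []
    params: list[tuple[FirstOrderParams, FirstOrderParams]] = []
    for _ in range(spec.n_subjects):
        on, off = sample_subject(population, rng)
        trials = np.stack(
            [
                generate_trial(on, off, protocol, baseline, noise_sd, rng, spec.dt).values
                for _ in range(spec.trials_per_subject)
            ]
        )
        avg = _moving_average(trials.mean(axis=0), spec.smoothing_window)
        n = avg.size
        times = np.arange(n) * spec.dt
        subjects.append(ResponseSeries(times, avg))
        params.append((on, off))
    stack = np.stack([s.values for s in subjects])
    times = subjects[0].times
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(subjects) > 1 else np.zeros_like(mean)
    return CohortResult(
        subjects=tuple(subjects),
        subject_params=tuple(params),
        ensemble_mean=ResponseSeries(times, mean),
        ensemble_sd=ResponseSeries(times, sd),
    )


def build_cohort(spec: CohortSpec, protocol: ExerciseProtocol) -> CohortStudy:
    """Generate the full synthetic study (both signals) deterministically.

    All randomness flows from ``spec.seed`` through one generator, so
    identical specs produce bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    hr = _one_signal(spec.hr_population, spec.baseline_hr, spec.noise_sd_hr, spec, protocol, rng)
    vo2 = _one_signal(
        spec.vo2_population, spec.baseline_vo2, spec.noise_sd_vo2, spec, protocol, rng
    )
    return CohortStudy(hr=hr, vo2=vo2, spec=spec)
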