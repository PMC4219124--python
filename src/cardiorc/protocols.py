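"""Treadmill exercise protocols and intensity-zone targets.

The study design behind this package uses piecewise-constant speed
schedules: a warm-up walk, one or more onset (running) bouts, and offset
(walking) recoveries.  Two canonical protocols are provided:

* a single-cycle square wave — warm-up 5 km/h for 4 min, onset 9 km/h for
  6 min, offset 5 km/h for at least 5 min; and
* an interval-training protocol — the same warm-up, three cycles of
  57 s at 9 km/h / 60 s at 5 km/h, then a cool-down walk.

Exercise intensity is prescribed in the moderate "aerobic zone",
70–77% of the age-predicted maximum heart rate (56–65% of VO2max),
where the HR–VO2 relationship is close to linear.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .errors import ProtocolError

__all__ = [
    "SegmentRole",
    "ProtocolSegment",
    "ExerciseProtocol",
    "IntensityZone",
    "hr_max",
    "aerobic_zone",
    "single_cycle_square_wave",
    "interval_training",
    "speed_at",
]


class SegmentRole(str, Enum):
    WARMUP = "warmup"
    ONSET = "onset"
    OFFSET = "offset"
    COOLDOWN = "cooldown"


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-speed stretch of a protocol.

    Attributes
    ----------
    role : SegmentRole
        Function of the segment in the protocol.
    speed : float
        Treadmill speed in km/h, non-negative.
    duration : float
        Segment length in seconds, strictly positive.
    """

    role: SegmentRole
    speed: float
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", SegmentRole(self.role))
        if self.duration <= 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")
        if self.speed < 0:
            raise ProtocolError(f"segment speed must be >= 0, got {self.speed}")


@dataclass(frozen=True)
class ExerciseProtocol:
    """An ordered, contiguous sequence of constant-speed segments.

    Invariants: the first segment is a warm-up, at least one onset segment
    is present, and segments tile [0, total_duration) without gaps.
    """

    segments: tuple[ProtocolSegment, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ProtocolError("protocol needs at least one segment")
        if segs[0].role is not SegmentRole.WARMUP:
            raise ProtocolError("first segment must be a warm-up")
        if not any(s.role is SegmentRole.ONSET for s in segs):
            raise ProtocolError("protocol needs at least one onset segment")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> list[float]:
        """Segment start times plus the final end time; partitions [0, T)."""
        edges = [0.0]
        for s in self.segments:
            edges.append(edges[-1] + s.duration)
        return edges

    def segment_windows(self) -> list[tuple[float, float, ProtocolSegment]]:
        """(start, end, segment) triples with half-open [start, end) windows."""
        edges = self.boundaries()
        return [(edges[i], edges[i + 1], s) for i, s in enumerate(self.segments)]

    def speed_at(self, t: float) -> float:
        return speed_at(self, t)

    # -- JSON interchange -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {"role": s.role.value, "speed_kmh": s.speed, "duration_s": s.duration}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExerciseProtocol":
        segs = [
            ProtocolSegment(SegmentRole(s["role"]), float(s["speed_kmh"]), float(s["duration_s"]))
            for s in d["segments"]
        ]
        return cls(tuple(segs), name=str(d.get("name", "protocol")))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExerciseProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class IntensityZone:
    """A training zone expressed as fractions of HRmax and VO2max."""

    hr_lo_frac: float
    hr_hi_frac: float
    vo2_lo_frac: float
    vo2_hi_frac: float

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.hr_lo_frac, self.hr_hi_frac, "HR"),
            (self.vo2_lo_frac, self.vo2_hi_frac, "VO2"),
        ):
            if not (0.0 < lo < hi < 1.0):
                raise ProtocolError(f"{what} zone fractions must satisfy 0 < lo < hi < 1")

    def hr_band(self, hrmax: float) -> tuple[float, float]:
        """Target HR band in bpm for a given individual HRmax."""
        return (self.hr_lo_frac * hrmax, self.hr_hi_frac * hrmax)


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate (Inbar), in beats per minute.

    HRmax = 205.8 − 0.685 · age.  Strictly decreasing in age; a warning is
    issued for ages outside the 10–100 year range where the regression was
    established.
    """
    if age <= 0:
        raise ProtocolError(f"age must be positive, got {age}")
    if not (10.0 <= age <= 100.0):
        warnings.warn(
            f"age {age} outside the 10-100 y range of the HRmax regression",
            stacklevel=2,
        )
    return 205.8 - 0.685 * age


def aerobic_zone() -> IntensityZone:
    """The moderate aerobic zone: 70–77% HRmax, 56–65% VO2max."""
    return IntensityZone(0.70, 0.77, 0.56, 0.65)


def single_cycle_square_wave(offset_duration: float = 300.0) -> ExerciseProtocol:
    """Single-cycle square-wave protocol.

    Warm-up 5 km/h for 240 s, onset 9 km/h for 360 s, then an offset walk at
    5 km/h for at least 300 s (default exactly 300 s; pass a longer
    ``offset_duration`` to extend the recovery window).
    """
    if offset_duration < 300.0:
        raise ProtocolError("offset walk lasts at least 5 minutes (300 s)")
    return ExerciseProtocol(
        (
            ProtocolSegment(SegmentRole.WARMUP, 5.0, 240.0),
            ProtocolSegment(SegmentRole.ONSET, 9.0, 360.0),
            ProtocolSegment(SegmentRole.OFFSET, 5.0, offset_duration),
        ),
        name="square-wave",
    )


def interval_training(cycles: int = 3, cooldown_duration: float = 300.0) -> ExerciseProtocol:
    """Interval-training protocol.

    Warm-up 5 km/h for 240 s, then ``cycles`` repetitions of 57 s at 9 km/h
    and 60 s at 5 km/h, then a cool-down walk at 5 km/h for at least 300 s.
    """
    if cycles < 1:
        raise ProtocolError(f"cycles must be >= 1, got {cycles}")
    if cooldown_duration < 300.0:
        raise ProtocolError("cool-down lasts at least 5 minutes (300 s)")
    segs: list[ProtocolSegment] = [ProtocolSegment(SegmentRole.WARMUP, 5.0, 240.0)]
    for _ in range(int(cycles)):
        segs.append(ProtocolSegment(SegmentRole.ONSET, 9.0, 57.0))
        segs.append(ProtocolSegment(SegmentRole.OFFSET, 5.0, 60.0))
    segs.append(ProtocolSegment(SegmentRole.COOLDOWN, 5.0, cooldown_duration))
    return ExerciseProtocol(tuple(segs), name="interval")


def speed_at(protocol: ExerciseProtocol, t: float) -> float:
    """Treadmill speed at time ``t`` (s), half-open [start, end) convention.

    At a switch instant the new segment's speed applies.  ``t`` equal to the
    total duration returns the final segment's speed.
    """
    total = protocol.total_duration
    if t < 0 or t > total:
        raise ProtocolError(f"t={t} outside protocol range [0, {total}]")
    if t == total:
        return protocol.segments[-1].speed
    for start, end, seg in protocol.segment_windows():
        if start <= t < end:
            return seg.speed
    raise ProtocolError(f"t={t} not covered by any segment")  # pragma: no cover
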