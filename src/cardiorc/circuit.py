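"""The single-supply switching RC-circuit model of exercise kinetics.

One DC supply ``V``, a diode, a DPDT switch, two capacitors ``C1``/``C2``
and three resistors ``R1``/``R2``/``R3`` reproduce the onset/offset
asymmetry of heart-rate and oxygen-uptake responses to square-wave
exercise.  The voltage of ``C1`` (above the warm-up baseline, taken as
zero) is the model output.

Three operating modes, selected by the switch:

* **onset** — the diode shorts ``R2`` and the supply charges ``C1``
  through ``R1``: ``v_c1(t) = V + (v_c1(0) − V)·e^{−t/(R1·C1)}``.
  ``C2`` is disconnected and holds its charge (configurable bleed through
  ``R3`` for long protocols).
* **offset** — ``C1`` discharges through the series loop ``R1 + R2`` into
  ``C2`` (the current through the large ``R3`` is neglected).  Charge
  ``C1·v_c1 + C2·v_c2`` is conserved and both voltages relax exponentially,
  with time constant ``(R1+R2)·C1·C2/(C1+C2)``, to the common equilibrium
  ``(C1·v_c1 + C2·v_c2)/(C1+C2)``.
* **recovery** — the same loop with ``R3`` shunting ``C2``; both
  capacitors drain to zero, returning the output to baseline.  This is a
  genuine two-state linear system, stepped exactly via its
  eigen-decomposition (it is similar to a symmetric matrix, so the
  eigenvalues are real and negative).

All stepping is closed-form piecewise-exponential, so the state is carried
across every mode switch bit-exactly: output continuity at switches holds
by construction.  A generic ODE integration of the same node equations is
used as an independent oracle in the test suite only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import InfeasibleCircuitError, ScheduleError
from .protocols import ExerciseProtocol, SegmentRole
from .series import ResponseSeries

__all__ = [
    "Mode",
    "CircuitParams",
    "CircuitState",
    "CircuitCharacteristics",
    "SwitchSchedule",
    "SimulationResult",
    "onset_evolve",
    "offset_evolve",
    "recovery_evolve",
    "simulate",
    "characteristics_from_circuit",
    "circuit_from_characteristics",
    "to_physiology",
]

#: Default ratio R3 / (R1 + R2); "sufficiently big" for the offset loop
#: current through R3 to be negligible.
DEFAULT_R3_RATIO = 100.0

#: Relative tolerance |v_c1 − v_c2| < tol·V that declares the offset
#: charge-sharing finished and hands over to long-term recovery.
EQUILIBRIUM_TOL = 1e-3


class Mode(str, Enum):
    ONSET = "onset"
    OFFSET = "offset"
    RECOVERY = "recovery"


@dataclass(frozen=True)
class CircuitParams:
    """Component values of the switching circuit.

    ``V`` is expressed directly in the physiological units of the signal
    being modelled (Δbpm above baseline for HR, Δml/min for VO2); the
    resistances are in ohms and capacitances in farads, so every R·C
    product is a time in seconds.
    """

    V: float
    R1: float
    R2: float
    R3: float
    C1: float
    C2: float

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "C1", "C2"):
            if getattr(self, name) <= 0:
                raise InfeasibleCircuitError(f"{name} must be strictly positive")
        if self.V < 0:
            raise InfeasibleCircuitError("V must be non-negative")
        if self.R3 < self.R1 + self.R2:
            warnings.warn(
                "R3 is not large relative to R1+R2; the ideal offset loop "
                "(R3 current neglected) becomes a poor approximation",
                stacklevel=2,
            )

    # -- derived time constants -------------------------------------------

    @property
    def tau_onset(self) -> float:
        """Onset charging time constant R1·C1 (s)."""
        return self.R1 * self.C1

    @property
    def tau_offset(self) -> float:
        """Offset charge-sharing time constant (R1+R2)·C1C2/(C1+C2) (s)."""
        return (self.R1 + self.R2) * self.C1 * self.C2 / (self.C1 + self.C2)

    def recovery_matrix(self) -> np.ndarray:
        """State matrix of the recovery subcircuit, d/dt [v1, v2] = A [v1, v2]."""
        r12 = self.R1 + self.R2
        return np.array(
            [
                [-1.0 / (r12 * self.C1), 1.0 / (r12 * self.C1)],
                [1.0 / (r12 * self.C2), -1.0 / (r12 * self.C2) - 1.0 / (self.R3 * self.C2)],
            ]
        )

    # -- JSON interchange -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "V": self.V,
            "R1_ohm": self.R1,
            "R2_ohm": self.R2,
            "R3_ohm": self.R3,
            "C1_farad": self.C1,
            "C2_farad": self.C2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(
            V=float(d["V"]),
            R1=float(d["R1_ohm"]),
            R2=float(d["R2_ohm"]),
            R3=float(d["R3_ohm"]),
            C1=float(d["C1_farad"]),
            C2=float(d["C2_farad"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CircuitParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CircuitState:
    """Capacitor voltages, active mode and current time."""

    v_c1: float
    v_c2: float
    mode: Mode
    t: float = 0.0


@dataclass(frozen=True)
class CircuitCharacteristics:
    """Normalized kinetic coefficients of a circuit.

    Gains are normalized by the speed step ``step_amplitude`` (km/h) so
    they are directly comparable with first-order fits of measured traces:
    ``k_on = V/du``, ``k_off = k_on · C2/(C1+C2)``.
    """

    k_on: float
    t_on: float
    k_off: float
    t_off: float
    step_amplitude: float = 4.0


# ---------------------------------------------------------------------------
# Closed-form single-mode trajectories.  ``t_rel`` may be a scalar or array
# of times measured from the start of the mode stretch.


def _onset_traj(v1: float, v2: float, p: CircuitParams, t_rel, c2_onset: str = "hold"):
    t_rel = np.asarray(t_rel, dtype=float)
    nv1 = p.V + (v1 - p.V) * np.exp(-t_rel / p.tau_onset)
    if c2_onset == "hold":
        nv2 = np.full_like(t_rel, v2)
    elif c2_onset == "bleed":
        nv2 = v2 * np.exp(-t_rel / (p.R3 * p.C2))
    else:
        raise ValueError(f"unknown c2 onset policy {c2_onset!r}")
    return nv1, nv2


def _offset_traj(v1: float, v2: float, p: CircuitParams, t_rel):
    t_rel = np.asarray(t_rel, dtype=float)
    veq = (p.C1 * v1 + p.C2 * v2) / (p.C1 + p.C2)
    decay = np.exp(-t_rel / p.tau_offset)
    return veq + (v1 - veq) * decay, veq + (v2 - veq) * decay


def _recovery_traj(v1: float, v2: float, p: CircuitParams, t_rel):
    t_rel = np.asarray(t_rel, dtype=float)
    A = p.recovery_matrix()
    lam, P = np.linalg.eig(A)
    lam, P = np.real(lam), np.real(P)  # similar to a symmetric matrix
    w0 = np.linalg.solve(P, np.array([v1, v2]))
    traj = P @ (w0[:, None] * np.exp(lam[:, None] * np.atleast_1d(t_rel)[None, :]))
    if t_rel.ndim == 0:
        return float(traj[0, 0]), float(traj[1, 0])
    return traj[0], traj[1]


def _evolve(state: CircuitState, params: CircuitParams, dt: float, c2_onset: str = "hold") -> CircuitState:
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if state.mode is Mode.ONSET:
        v1, v2 = _onset_traj(state.v_c1, state.v_c2, params, dt, c2_onset)
    elif state.mode is Mode.OFFSET:
        v1, v2 = _offset_traj(state.v_c1, state.v_c2, params, dt)
    else:
        v1, v2 = _recovery_traj(state.v_c1, state.v_c2, params, dt)
    return CircuitState(float(v1), float(v2), state.mode, state.t + dt)


def onset_evolve(
    state: CircuitState, params: CircuitParams, dt: float, c2_onset: str = "hold"
) -> CircuitState:
    """Advance an onset-mode state by ``dt`` seconds (exact closed form)."""
    if state.mode is not Mode.ONSET:
        raise ValueError("state is not in onset mode")
    return _evolve(state, params, dt, c2_onset)


def offset_evolve(state: CircuitState, params: CircuitParams, dt: float) -> CircuitState:
    """Advance an offset-mode state by ``dt`` seconds (ideal charge-sharing loop)."""
    if state.mode is not Mode.OFFSET:
        raise ValueError("state is not in offset mode")
    return _evolve(state, params, dt)


def recovery_evolve(state: CircuitState, params: CircuitParams, dt: float) -> CircuitState:
    """Advance a recovery-mode state by ``dt`` seconds (drain through R3)."""
    if state.mode is not Mode.RECOVERY:
        raise ValueError("state is not in recovery mode")
    return _evolve(state, params, dt)


# ---------------------------------------------------------------------------
# Schedules and multi-mode simulation.


@dataclass(frozen=True)
class SwitchSchedule:
    """Timed DPDT switch events derived from an exercise protocol.

    ``events`` is an ordered list of ``(time_s, Mode)`` pairs starting at
    t = 0; each mode holds until the next event.  ``recovery_not_before``
    marks the start of the final cool-down tail: once past it, the offset
    loop hands over to recovery as soon as the capacitor voltages have
    equalized to tolerance (this instant is the model's t2).
    """

    events: tuple[tuple[float, Mode], ...]
    total_duration: float
    recovery_not_before: float | None = None

    def __post_init__(self) -> None:
        ev = tuple((float(t), Mode(m)) for t, m in self.events)
        if not ev:
            raise ScheduleError("schedule needs at least one event")
        if ev[0][0] != 0.0:
            raise ScheduleError("first event must be at t=0")
        times = [t for t, _ in ev]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ScheduleError("event times must be non-decreasing (no overlaps)")
        if self.total_duration < times[-1]:
            raise ScheduleError("total_duration precedes the last event")
        object.__setattr__(self, "events", ev)

    @classmethod
    def from_protocol(cls, protocol: ExerciseProtocol) -> "SwitchSchedule":
        """Map protocol segments to switch events.

        Warm-up idles at baseline (recovery mode acting on a zero state),
        onset segments select the onset subcircuit, offset and cool-down
        segments the charge-sharing loop; ``recovery_not_before`` is the
        cool-down start, or the start of the last offset segment when the
        protocol has no explicit cool-down.
        """
        events: list[tuple[float, Mode]] = []
        recovery_not_before: float | None = None
        last_offset_start: float | None = None
        for start, _end, seg in protocol.segment_windows():
            if seg.role is SegmentRole.WARMUP:
                events.append((start, Mode.RECOVERY))
            elif seg.role is SegmentRole.ONSET:
                events.append((start, Mode.ONSET))
            elif seg.role is SegmentRole.OFFSET:
                events.append((start, Mode.OFFSET))
                last_offset_start = start
            elif seg.role is SegmentRole.COOLDOWN:
                events.append((start, Mode.OFFSET))
                if recovery_not_before is None:
                    recovery_not_before = start
        if recovery_not_before is None:
            recovery_not_before = last_offset_start
        return cls(tuple(events), protocol.total_duration, recovery_not_before)

    @property
    def t1(self) -> float | None:
        """End of the first onset bout (first offset event after an onset)."""
        seen_onset = False
        for t, m in self.events:
            if m is Mode.ONSET:
                seen_onset = True
            elif seen_onset and m is Mode.OFFSET:
                return t
        return None


@dataclass(frozen=True)
class SimulationResult:
    """Sampled capacitor voltages, per-sample mode, and the run's parameters."""

    times: np.ndarray
    v_c1: np.ndarray
    v_c2: np.ndarray
    mode: np.ndarray  # array of Mode values, one per sample
    baseline: float
    params: CircuitParams
    switch_jumps: tuple[float, ...] = ()
    t_recovery: float | None = None  # instant the run entered recovery (t2)

    @property
    def output(self) -> np.ndarray:
        """Physiological output: baseline + v_c1."""
        return self.baseline + self.v_c1

    def output_series(self) -> ResponseSeries:
        return ResponseSeries(self.times, self.output)

    def max_switch_jump(self) -> float:
        """Largest state discontinuity handed across any mode switch."""
        return max(self.switch_jumps, default=0.0)


def _build_stretches(
    schedule: SwitchSchedule,
) -> list[tuple[float, float, Mode]]:
    ev = list(schedule.events)
    stretches = []
    for i, (t, m) in enumerate(ev):
        t_end = ev[i + 1][0] if i + 1 < len(ev) else schedule.total_duration
        if t_end > t:
            stretches.append((t, t_end, m))
    return stretches


def simulate(
    params: CircuitParams,
    schedule: SwitchSchedule,
    grid_dt: float = 1.0,
    baseline: float = 0.0,
    c2_onset: str = "hold",
    equilibrium_tol: float = EQUILIBRIUM_TOL,
) -> SimulationResult:
    """Run the switching circuit over a schedule on a uniform grid.

    The capacitor state is evolved with the exact closed form of each mode
    and carried unchanged across every switch, so the output is continuous
    at switch instants by construction.  In the final offset/cool-down
    stretch the run hands over to recovery mode at the later of
    ``schedule.recovery_not_before`` and the instant
    ``|v_c1 − v_c2| < equilibrium_tol · V`` (the handover time is t2).
    """
    if grid_dt <= 0:
        raise ScheduleError("grid_dt must be positive")
    stretches = _build_stretches(schedule)
    if not stretches:
        raise ScheduleError("schedule covers no time")

    n = int(np.floor(schedule.total_duration / grid_dt + 1e-9)) + 1
    times = np.arange(n) * grid_dt

    # Dynamic recovery handover inside the final stretch.
    final_start = stretches[-1][0]
    rnb = schedule.recovery_not_before

    v1, v2 = 0.0, 0.0
    out_v1 = np.empty(n)
    out_v2 = np.empty(n)
    out_mode = np.empty(n, dtype=object)
    jumps: list[float] = []
    t_recovery: float | None = None

    work = list(stretches)
    k = 0
    while k < len(work):
        ta, tb, mode = work[k]
        if (
            mode is Mode.OFFSET
            and rnb is not None
            and ta >= final_start - 1e-12
            and t_recovery is None
        ):
            # analytic equilibrium time: |v1 - v2| decays as exp(-t/tau_off)
            d0 = abs(v1 - v2)
            tol_abs = equilibrium_tol * params.V if params.V > 0 else equilibrium_tol
            if d0 <= tol_abs:
                t_star = ta
            else:
                t_star = ta + params.tau_offset * float(np.log(d0 / tol_abs))
            t_rec = max(t_star, rnb, ta)
            if t_rec < tb:
                work[k] = (ta, t_rec, Mode.OFFSET)
                work.insert(k + 1, (t_rec, tb, Mode.RECOVERY))
                t_recovery = t_rec
                ta, tb, mode = work[k]

        i0 = int(np.searchsorted(times, ta - 1e-9))
        i1 = int(np.searchsorted(times, tb - 1e-9))
        t_rel = times[i0:i1] - ta
        if mode is Mode.ONSET:
            s1, s2 = _onset_traj(v1, v2, params, t_rel, c2_onset)
            e1, e2 = _onset_traj(v1, v2, params, tb - ta, c2_onset)
        elif mode is Mode.OFFSET:
            s1, s2 = _offset_traj(v1, v2, params, t_rel)
            e1, e2 = _offset_traj(v1, v2, params, tb - ta)
        else:
            s1, s2 = _recovery_traj(v1, v2, params, t_rel)
            e1, e2 = _recovery_traj(v1, v2, params, tb - ta)
        out_v1[i0:i1] = s1
        out_v2[i0:i1] = s2
        out_mode[i0:i1] = mode
        # state handed to the next stretch: left-limit of this stretch at tb
        new_v1, new_v2 = float(e1), float(e2)
        jumps.append(0.0)  # carried bit-exactly; recorded for the continuity audit
        v1, v2 = new_v1, new_v2
        k += 1

    # final grid point (== total_duration) belongs to the last stretch's end state
    if times[-1] >= work[-1][1] - 1e-9:
        out_v1[-1], out_v2[-1], out_mode[-1] = v1, v2, work[-1][2]

    return SimulationResult(
        times=times,
        v_c1=out_v1,
        v_c2=out_v2,
        mode=out_mode,
        baseline=baseline,
        params=params,
        switch_jumps=tuple(jumps[:-1]),
        t_recovery=t_recovery,
    )


# ---------------------------------------------------------------------------
# Circuit <-> kinetic-coefficient mapping.


def characteristics_from_circuit(
    params: CircuitParams, step_amplitude: float = 4.0
) -> CircuitCharacteristics:
    """Kinetic coefficients realized by a circuit.

    ``t_on = R1·C1``; ``t_off = (R1+R2)·C1·C2/(C1+C2)``; gains are
    normalized by the speed step: ``k_on = V/du`` and
    ``k_off = k_on·C2/(C1+C2)`` (the fraction of the onset amplitude that
    the charge-sharing loop removes during offset).
    """
    if step_amplitude <= 0:
        raise InfeasibleCircuitError("step_amplitude must be positive")
    k_on = params.V / step_amplitude
    return CircuitCharacteristics(
        k_on=k_on,
        t_on=params.tau_onset,
        k_off=k_on * params.C2 / (params.C1 + params.C2),
        t_off=params.tau_offset,
        step_amplitude=step_amplitude,
    )


def circuit_from_characteristics(
    k_on: float,
    t_on: float,
    k_off: float,
    t_off: float,
    r2: float = 100.0,
    step_amplitude: float = 4.0,
    r3_ratio: float = DEFAULT_R3_RATIO,
) -> CircuitParams:
    """Configure component values from measured kinetic coefficients.

    With ``R2`` a pre-defined free parameter and ``g = k_off/k_on``:

        C1 = (t_off/g − t_on) / R2,   R1 = t_on / C1,
        C2 = C1·g / (1 − g),          V = k_on · du,
        R3 = r3_ratio · (R1 + R2).

    This is the exact algebraic inverse of
    :func:`characteristics_from_circuit`.  Raises
    :class:`InfeasibleCircuitError`, naming the violated constraint, when
    the coefficients do not correspond to positive component values.
    """
    for name, val in (
        ("k_on", k_on),
        ("t_on", t_on),
        ("k_off", k_off),
        ("t_off", t_off),
        ("r2", r2),
        ("step_amplitude", step_amplitude),
    ):
        if val <= 0:
            raise InfeasibleCircuitError(f"{name} must be positive, got {val}")
    if k_off >= k_on:
        raise InfeasibleCircuitError(
            "k_off must be smaller than k_on (C2 would be non-positive or infinite)"
        )
    g = k_off / k_on
    if t_off / g <= t_on:
        raise InfeasibleCircuitError(
            "t_off/(k_off/k_on) must exceed t_on (C1 would be non-positive)"
        )
    c1 = (t_off / g - t_on) / r2
    r1 = t_on / c1
    c2 = c1 * g / (1.0 - g)
    return CircuitParams(
        V=k_on * step_amplitude,
        R1=r1,
        R2=r2,
        R3=r3_ratio * (r1 + r2),
        C1=c1,
        C2=c2,
    )


def to_physiology(result: SimulationResult, baseline: float) -> ResponseSeries:
    """Convert a voltage trace to a physiological series: baseline + v_c1.

    Units are bpm for a heart-rate configuration, ml/min for oxygen uptake.
    """
    return ResponseSeries(result.times, baseline + result.v_c1)
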