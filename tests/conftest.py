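"""Shared fixtures and the independent ODE oracle.

The oracle integrates each subcircuit's node equations with a generic
adaptive ODE solver; it deliberately shares no code with the closed-form
piecewise-exponential stepping it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiorc import (
    CircuitParams,
    ExerciseProtocol,
    ProtocolSegment,
    SwitchSchedule,
    circuit_from_characteristics,
)
from cardiorc.reference import HR_POPULATION, VO2_POPULATION


def integrate_mode(
    params: CircuitParams,
    mode: str,
    v0: tuple[float, float],
    t_grid: np.ndarray,
    c2_onset: str = "hold",
) -> tuple[np.ndarray, np.ndarray]:
    """Reference trajectories of one subcircuit by generic numeric integration."""
    r12 = params.R1 + params.R2

    if mode == "onset":
        if c2_onset == "hold":
            def rhs(t, y):
                return [(params.V - y[0]) / (params.R1 * params.C1), 0.0]
        else:
            def rhs(t, y):
                return [
                    (params.V - y[0]) / (params.R1 * params.C1),
                    -y[1] / (params.R3 * params.C2),
                ]
    elif mode == "offset":
        def rhs(t, y):
            i = (y[0] - y[1]) / r12
            return [-i / params.C1, i / params.C2]
    elif mode == "recovery":
        def rhs(t, y):
            i = (y[0] - y[1]) / r12
            return [-i / params.C1, i / params.C2 - y[1] / (params.R3 * params.C2)]
    else:
        raise ValueError(mode)

    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        list(v0),
        t_eval=t_grid,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    assert sol.success
    return sol.y[0], sol.y[1]


@pytest.fixture(scope="session")
def ode_oracle():
    return integrate_mode


@pytest.fixture(scope="session")
def hr_circuit_from_means() -> CircuitParams:
    """Circuit configured from the HR population means (R2=100, du=4)."""
    p = HR_POPULATION
    return circuit_from_characteristics(
        p.k_on_mean, p.t_on_mean, p.k_off_mean, p.t_off_mean, r2=100.0, step_amplitude=4.0
    )


@pytest.fixture(scope="session")
def vo2_circuit_from_means() -> CircuitParams:
    p = VO2_POPULATION
    return circuit_from_characteristics(
        p.k_on_mean, p.t_on_mean, p.k_off_mean, p.t_off_mean, r2=100.0, step_amplitude=4.0
    )


@pytest.fixture(scope="session")
def settling_protocol() -> ExerciseProtocol:
    """Square wave with a settling-length onset (15 T_on) and an offset short
    enough to remain pure charge-sharing — the identification protocol for
    noise-free round trips."""
    return ExerciseProtocol(
        (
            ProtocolSegment("warmup", 5.0, 240.0),
            ProtocolSegment("onset", 9.0, 900.0),
            ProtocolSegment("offset", 5.0, 420.0),
        ),
        name="settling-square-wave",
    )


def random_feasible_characteristics(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Draw (k_on, t_on, k_off, t_off) that map to a realizable circuit."""
    k_on = rng.uniform(1.0, 500.0)
    g = rng.uniform(0.3, 0.97)
    t_on = rng.uniform(10.0, 150.0)
    t_off = g * t_on * rng.uniform(1.05, 3.0)
    return k_on, t_on, k_on * g, t_off


def random_params(rng: np.random.Generator) -> CircuitParams:
    return CircuitParams(
        V=rng.uniform(1.0, 60.0),
        R1=rng.uniform(20.0, 300.0),
        R2=rng.uniform(20.0, 300.0),
        R3=rng.uniform(5e3, 1e5),
        C1=rng.uniform(0.05, 2.0),
        C2=rng.uniform(0.05, 5.0),
    )
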