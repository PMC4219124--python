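"""Published reference values for moderate treadmill exercise.

Population kinetics (mean and STD of the first-order onset/offset
coefficients) for heart rate and oxygen uptake in untrained healthy
adults performing the single-cycle square-wave protocol (5 → 9 km/h,
a 4 km/h speed step into the 70–77% HRmax aerobic zone), together with
the tuned switching-circuit component values that reproduce the averaged
responses.  These serve as defaults for the synthetic-cohort generator
and as worked-example inputs.
"""

from __future__ import annotations

from .circuit import CircuitParams
from .first_order import PopulationSummary

__all__ = [
    "STEP_AMPLITUDE_KMH",
    "DEFAULT_R2_OHM",
    "HR_POPULATION",
    "VO2_POPULATION",
    "HR_CIRCUIT",
    "VO2_CIRCUIT",
    "DEFAULT_BASELINE_HR",
    "DEFAULT_BASELINE_VO2",
]

#: Speed step of the square-wave protocols (9 − 5 km/h).
STEP_AMPLITUDE_KMH = 4.0

#: Free resistance parameter conventionally fixed when configuring a circuit.
DEFAULT_R2_OHM = 100.0

#: Heart-rate kinetics (T in s, K in bpm per km/h), 20-subject cohort.
HR_POPULATION = PopulationSummary(
    t_on_mean=60.60, t_on_sd=17.52,
    k_on_mean=13.35, k_on_sd=2.26,
    t_off_mean=88.99, t_off_sd=39.08,
    k_off_mean=10.15, k_off_sd=1.87,
)

#: Oxygen-uptake kinetics (T in s, K in ml/min per km/h), same cohort.
VO2_POPULATION = PopulationSummary(
    t_on_mean=54.97, t_on_sd=10.78,
    k_on_mean=356.43, k_on_sd=60.12,
    t_off_mean=65.90, t_off_sd=13.43,
    k_off_mean=340.30, k_off_sd=57.93,
)

#: Tuned circuit for the averaged heart-rate response (V in Δbpm).
HR_CIRCUIT = CircuitParams(
    V=55.11319,
    R1=100.9028,
    R2=100.0,
    R3=100.0 * (100.9028 + 100.0),
    C1=0.6430,
    C2=1.7782,
)

#: Tuned circuit for the averaged oxygen-uptake response (V in Δml/min).
VO2_CIRCUIT = CircuitParams(
    V=1319.0,
    R1=248.3758,
    R2=100.0,
    R3=100.0 * (248.3758 + 100.0),
    C1=0.1916,
    C2=3.8900,
)

#: Plausible resting/warm-up baselines used by examples and the cohort
#: generator (the model itself works on amplitudes above baseline).
DEFAULT_BASELINE_HR = 90.0
DEFAULT_BASELINE_VO2 = 900.0
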