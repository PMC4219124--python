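"""Identify onset/offset kinetics from a (synthetic) recorded trace.

Generates one noisy treadmill trial for a subject with known first-order
coefficients, fits the onset rise and the offset decay, and compares the
estimates with the truth.
"""

import numpy as np

from cardiorc import (
    ExerciseProtocol,
    FirstOrderParams,
    ProtocolSegment,
    generate_trial,
    identify_onset_offset,
)

protocol = ExerciseProtocol(
    (
        ProtocolSegment("warmup", 5.0, 240.0),
        ProtocolSegment("onset", 9.0, 900.0),
        ProtocolSegment("offset", 5.0, 420.0),
    ),
    name="settling-square-wave",
)

truth_on = FirstOrderParams(K=13.35, T=60.60)   # bpm per km/h, s
truth_off = FirstOrderParams(K=10.15, T=88.99)
rng = np.random.default_rng(42)
trial = generate_trial(truth_on, truth_off, protocol, baseline=90.0, noise_sd=2.0, rng=rng)

fit_on, fit_off = identify_onset_offset(trial, protocol)
print(f"onset:  K = {fit_on.K:6.2f} (true 13.35)   T = {fit_on.T:6.2f} s (true 60.60)")
print(f"offset: K = {fit_off.K:6.2f} (true 10.15)   T = {fit_off.T:6.2f} s (true 88.99)")

# K is the steady-state gain (response change per km/h of speed step), T the
# e-folding time.  With 2 bpm of measurement noise on a 53 bpm excursion the
# estimates land within a few percent of the generating values.
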