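"""Configure circuit components from measured kinetic coefficients.

Maps the heart-rate population means (onset/offset gains and time
constants) to component values with R2 fixed at 100 ohm and a 4 km/h speed
step, then verifies the mapping inverts exactly.
"""

from cardiorc import characteristics_from_circuit, circuit_from_characteristics
from cardiorc.reference import HR_POPULATION as pop

params = circuit_from_characteristics(
    pop.k_on_mean, pop.t_on_mean, pop.k_off_mean, pop.t_off_mean,
    r2=100.0, step_amplitude=4.0,
)
print("configured circuit from HR means (K_on=13.35, T_on=60.60, K_off=10.15, T_off=88.99):")
print(f"  V  = {params.V:10.4f}   (supply, bpm above baseline = K_on x 4 km/h)")
print(f"  R1 = {params.R1:10.4f} ohm")
print(f"  R2 = {params.R2:10.4f} ohm  (free parameter, fixed)")
print(f"  R3 = {params.R3:10.1f} ohm  (100 x (R1+R2), recovery drain)")
print(f"  C1 = {params.C1:10.4f} F    (fast store: the response itself)")
print(f"  C2 = {params.C2:10.4f} F    (slow store: post-exercise storage)")

back = characteristics_from_circuit(params, step_amplitude=4.0)
print("\nround trip through the circuit:")
print(f"  K_on = {back.k_on:.4f}, T_on = {back.t_on:.4f} s, "
      f"K_off = {back.k_off:.4f}, T_off = {back.t_off:.4f} s")

# The onset time constant is R1*C1; the offset one is (R1+R2)*C1C2/(C1+C2).
# The gain ratio K_off/K_on equals C2/(C1+C2): the larger C2 is, the more of
# the exercise amplitude the offset loop removes.
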