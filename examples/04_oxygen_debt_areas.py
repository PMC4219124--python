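"""Quantify oxygen credits, deficit, debt, and the extra storage area.

Runs the tuned averaged HR circuit through a single square-wave cycle long
enough for the post-exercise charge sharing to finish, then integrates the
energy areas of the cycle.
"""

from cardiorc import SwitchSchedule, compute_areas, simulate, single_cycle_square_wave, storage_balance
from cardiorc.reference import HR_CIRCUIT

protocol = single_cycle_square_wave(offset_duration=900)
result = simulate(HR_CIRCUIT, SwitchSchedule.from_protocol(protocol))
areas = compute_areas(result)
released, gained = storage_balance(result)

print(f"credits       = {areas.credits:9.1f} bpm*s  (delivered during the bout)")
print(f"deficit       = {areas.deficit:9.1f} bpm*s  (shortfall while HR lags the step)")
print(f"offset total  = {areas.offset_total:9.1f} bpm*s  (post-exercise excess)")
print(f"debt          = {areas.debt:9.1f} bpm*s  (the part repaying the deficit)")
print(f"storage extra = {areas.storage_extra:9.1f} bpm*s  (beyond repayment -> storage)")
print(f"C1 charge released = {released:.3f}, C2 charge gained = {gained:.3f}")

# offset_total exceeds the deficit because the offset time constant is longer
# than the onset one: post-exercise metabolism does more than repay the onset
# shortfall.  The surplus is mirrored by the charge C2 accumulates -- the
# circuit analogue of an energy-storage process such as glycogenesis.
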