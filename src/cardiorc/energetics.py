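"""Electronic quantification of oxygen 'credits', 'deficit' and 'debt'.

With cardiac output Q = SV × HR and stroke volume SV constant at moderate
intensity, time integrals of the model output are proportional to
delivered energy.  Over a single onset/offset cycle (areas in
response-unit·seconds on the v_c1 trace):

* **credits** — the area under v_c1 during the onset bout: energy actually
  delivered while the response climbs toward the supply plateau V.
* **deficit** — the complementary area (V − v_c1) over the onset bout: the
  shortfall while the response lags the demand step.
* **offset_total** — the area of the post-exercise excess, v_c1 above its
  end-of-offset equilibrium value, between t1 (exercise stop) and t2
  (capacitor voltages equalized).
* **debt** — by definition the part of offset_total that repays the
  deficit: min(deficit, offset_total).
* **storage_extra** — offset_total − debt.  Because the offset time
  constant exceeds the onset one, this residual is positive: post-exercise
  metabolism above baseline does more than repay the onset deficit, which
  the model attributes to an energy-storage process (the charge C2
  accumulates, the circuit analogue of glycogenesis).
* **c2_stored_area** — the corresponding accumulation area of v_c2 over
  the offset window.

Quadrature is trapezoidal on the simulation grid (dt ≤ 1 s); the
integrands are smooth exponentials so quadrature error is far below the
modelled effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Mode, SimulationResult, SwitchSchedule
from .errors import CardioRCError

__all__ = ["EnergyAreas", "compute_areas", "storage_balance"]


@dataclass(frozen=True)
class EnergyAreas:
    """Integrated energy areas of one onset/offset cycle (unit·s)."""

    credits: float
    deficit: float
    offset_total: float
    debt: float
    storage_extra: float
    c2_stored_area: float
    sv: float = 1.0  # stroke-volume scale; Q-integral = sv * area

    def __post_init__(self) -> None:
        for name in ("credits", "deficit", "offset_total", "debt", "c2_stored_area"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be non-negative")
        if self.debt > self.offset_total + 1e-9:
            raise ValueError("debt cannot exceed offset_total")


def _mode_blocks(result: SimulationResult, mode: Mode) -> list[tuple[int, int]]:
    """Contiguous index blocks [i0, i1] (inclusive) where result.mode == mode."""
    is_m = np.array([m is mode for m in result.mode])
    blocks = []
    i = 0
    n = is_m.size
    while i < n:
        if is_m[i]:
            j = i
            while j + 1 < n and is_m[j + 1]:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    return blocks


def compute_areas(
    result: SimulationResult,
    schedule: SwitchSchedule | None = None,
    sv: float = 1.0,
    reference: str = "equilibrium",
) -> EnergyAreas:
    """Integrate the energy areas of the first complete onset/offset cycle.

    The result must contain one onset window followed by an offset window
    that reached the charge-sharing equilibrium (i.e. the run entered
    recovery mode); otherwise an error asks for a longer schedule.  The
    offset areas are referenced to v_c1(t2) by default; pass
    ``reference="baseline"`` to reference them to the pre-exercise zero
    baseline instead.
    """
    del schedule  # windows are reconstructed from the per-sample mode labels
    if reference not in ("equilibrium", "baseline"):
        raise ValueError("reference must be 'equilibrium' or 'baseline'")
    onset_blocks = _mode_blocks(result, Mode.ONSET)
    if not onset_blocks:
        raise CardioRCError("no onset window in the simulation result")
    i_on0, i_on1 = onset_blocks[0]
    # onset window includes its right edge (the offset switch sample, t1)
    i_t1 = min(i_on1 + 1, result.times.size - 1)

    t_on = result.times[i_on0 : i_t1 + 1]
    v_on = result.v_c1[i_on0 : i_t1 + 1]
    credits = float(np.trapezoid(v_on, t_on))
    onset_span = float(t_on[-1] - t_on[0])
    deficit = result.params.V * onset_span - credits

    offset_blocks = [b for b in _mode_blocks(result, Mode.OFFSET) if b[0] >= i_on1]
    if not offset_blocks:
        if result.mode[i_t1] is Mode.RECOVERY:
            # charge-sharing finished instantly (zero-length offset window)
            return EnergyAreas(
                credits=credits,
                deficit=deficit,
                offset_total=0.0,
                debt=0.0,
                storage_extra=0.0,
                c2_stored_area=0.0,
                sv=sv,
            )
        raise CardioRCError("no offset window after the onset")
    i_off0, i_off1 = offset_blocks[0]
    recovery_after = any(
        m is Mode.RECOVERY for m in result.mode[i_off1 + 1 : i_off1 + 2]
    )
    if not recovery_after:
        raise CardioRCError(
            "offset did not reach the equilibrium tolerance; "
            "extend the offset/cool-down segment of the schedule"
        )
    # t2 = last sample still on the ideal charge-sharing trajectory (the
    # following sample is already evolving under the R3 drain)
    i_t2 = i_off1

    t_off = result.times[i_t1 : i_t2 + 1]
    v_off = result.v_c1[i_t1 : i_t2 + 1]
    ref = float(result.v_c1[i_t2]) if reference == "equilibrium" else 0.0
    offset_total = float(np.trapezoid(v_off - ref, t_off))

    v2_off = result.v_c2[i_t1 : i_t2 + 1]
    c2_area = float(np.trapezoid(v2_off - v2_off[0], t_off))

    debt = min(deficit, offset_total)
    return EnergyAreas(
        credits=credits,
        deficit=deficit,
        offset_total=offset_total,
        debt=debt,
        storage_extra=offset_total - debt,
        c2_stored_area=c2_area,
        sv=sv,
    )


def storage_balance(result: SimulationResult) -> tuple[float, float]:
    """Charge released by C1 vs charge gained by C2 over the offset window.

    Returns ``(C1·(v1(t1) − v1(t2)), C2·(v2(t2) − v2(t1)))``.  In the ideal
    charge-sharing loop the two are equal (conservation); a zero-length
    offset yields (0, 0).
    """
    onset_blocks = _mode_blocks(result, Mode.ONSET)
    offset_blocks = _mode_blocks(result, Mode.OFFSET)
    if onset_blocks:
        offset_blocks = [b for b in offset_blocks if b[0] >= onset_blocks[0][1]]
    if not offset_blocks:
        return (0.0, 0.0)
    i0, i1 = offset_blocks[0]
    i_t2 = i1  # last sample of the ideal charge-sharing window
    p = result.params
    released = p.C1 * float(result.v_c1[i0] - result.v_c1[i_t2])
    gained = p.C2 * float(result.v_c2[i_t2] - result.v_c2[i0])
    return (released, gained)
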