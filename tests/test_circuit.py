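"""Switching-circuit stepping, schedules, and the coefficient mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiorc import (
    CircuitParams,
    CircuitState,
    InfeasibleCircuitError,
    Mode,
    ScheduleError,
    SwitchSchedule,
    characteristics_from_circuit,
    circuit_from_characteristics,
    identify_onset_offset,
    interval_training,
    offset_evolve,
    onset_evolve,
    recovery_evolve,
    simulate,
    single_cycle_square_wave,
    to_physiology,
)
from cardiorc.reference import HR_CIRCUIT, HR_POPULATION, VO2_CIRCUIT, VO2_POPULATION

from conftest import random_feasible_characteristics, random_params


class TestOnsetEvolve:
    def test_zero_supply_zero_state_stays_zero(self):
        p = CircuitParams(V=0.0, R1=100.0, R2=100.0, R3=2e4, C1=0.5, C2=1.5)
        s = onset_evolve(CircuitState(0.0, 0.0, Mode.ONSET), p, 100.0)
        assert s.v_c1 == 0.0 and s.v_c2 == 0.0

    def test_long_horizon_reaches_printed_hr_supply(self):
        s = CircuitState(0.0, 0.0, Mode.ONSET)
        s = onset_evolve(s, HR_CIRCUIT, 40 * HR_CIRCUIT.tau_onset)
        assert s.v_c1 == pytest.approx(55.11319, rel=1e-9)

    def test_c2_held_by_default_and_bleeds_on_request(self):
        s0 = CircuitState(10.0, 5.0, Mode.ONSET)
        held = onset_evolve(s0, HR_CIRCUIT, 60.0)
        assert held.v_c2 == 5.0
        bled = onset_evolve(s0, HR_CIRCUIT, 60.0, c2_onset="bleed")
        assert 0.0 < bled.v_c2 < 5.0

    def test_matches_ode_oracle(self, ode_oracle):
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = random_params(rng)
            t = np.linspace(0.0, 5 * p.tau_onset, 30)
            v0 = (rng.uniform(0, p.V), rng.uniform(0, p.V))
            ref1, ref2 = ode_oracle(p, "onset", v0, t)
            got = [onset_evolve(CircuitState(*v0, Mode.ONSET), p, ti) for ti in t]
            assert np.abs([g.v_c1 for g in got] - ref1).max() < 1e-8
            assert np.abs([g.v_c2 for g in got] - ref2).max() < 1e-8


class TestOffsetEvolve:
    def test_equilibrium_is_fixed_point(self):
        s0 = CircuitState(12.5, 12.5, Mode.OFFSET)
        s = offset_evolve(s0, HR_CIRCUIT, 500.0)
        assert s.v_c1 == pytest.approx(12.5, abs=1e-12)
        assert s.v_c2 == pytest.approx(12.5, abs=1e-12)

    def test_charge_conservation_along_trajectory(self):
        p = HR_CIRCUIT
        q0 = p.C1 * 55.1
        s = CircuitState(55.1, 0.0, Mode.OFFSET)
        for dt in (1.0, 10.0, 100.0, 1000.0):
            s = offset_evolve(s, p, dt)
            q = p.C1 * s.v_c1 + p.C2 * s.v_c2
            assert q == pytest.approx(q0, rel=1e-12)

    def test_common_equilibrium_from_charge_split(self):
        p = HR_CIRCUIT
        s = offset_evolve(CircuitState(55.1, 0.0, Mode.OFFSET), p, 50 * p.tau_offset)
        veq = 55.1 * p.C1 / (p.C1 + p.C2)
        assert s.v_c1 == pytest.approx(veq, rel=1e-9)
        assert s.v_c2 == pytest.approx(veq, rel=1e-9)

    def test_matches_ode_oracle(self, ode_oracle):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_params(rng)
            t = np.linspace(0.0, 5 * p.tau_offset, 30)
            v0 = (rng.uniform(0, 60), rng.uniform(0, 60))
            ref1, ref2 = ode_oracle(p, "offset", v0, t)
            got = [offset_evolve(CircuitState(*v0, Mode.OFFSET), p, ti) for ti in t]
            assert np.abs([g.v_c1 for g in got] - ref1).max() < 1e-8
            assert np.abs([g.v_c2 for g in got] - ref2).max() < 1e-8


class TestRecoveryEvolve:
    def test_zero_state_stays_zero(self):
        s = recovery_evolve(CircuitState(0.0, 0.0, Mode.RECOVERY), HR_CIRCUIT, 100.0)
        assert s.v_c1 == 0.0 and s.v_c2 == 0.0

    def test_energy_strictly_decreases(self):
        p = HR_CIRCUIT
        s = CircuitState(14.0, 14.0, Mode.RECOVERY)
        e_prev = 0.5 * p.C1 * s.v_c1**2 + 0.5 * p.C2 * s.v_c2**2
        for _ in range(10):
            s = recovery_evolve(s, p, 200.0)
            e = 0.5 * p.C1 * s.v_c1**2 + 0.5 * p.C2 * s.v_c2**2
            assert e < e_prev
            e_prev = e

    def test_long_horizon_drains_to_baseline(self):
        p = HR_CIRCUIT
        # slow recovery eigenmode ~ R3 (C1 + C2)
        tau_slow = p.R3 * (p.C1 + p.C2)
        s = recovery_evolve(CircuitState(14.0, 14.0, Mode.RECOVERY), p, 25 * tau_slow)
        assert abs(s.v_c1) < 1e-6 * 14.0 and abs(s.v_c2) < 1e-6 * 14.0

    def test_matches_ode_oracle(self, ode_oracle):
        rng = np.random.default_rng(13)
        for _ in range(5):
            p = random_params(rng)
            # window covering the fast charge-sharing mode and the start of
            # the slow drain; longer spans accumulate integrator error above
            # the comparison floor
            tau_slow = p.R3 * (p.C1 + p.C2)
            t = np.linspace(0.0, min(0.5 * tau_slow, 20 * p.tau_offset), 30)
            v0 = (rng.uniform(0, 60), rng.uniform(0, 60))
            ref1, ref2 = ode_oracle(p, "recovery", v0, t)
            got = [recovery_evolve(CircuitState(*v0, Mode.RECOVERY), p, ti) for ti in t]
            assert np.abs([g.v_c1 for g in got] - ref1).max() < 1e-8
            assert np.abs([g.v_c2 for g in got] - ref2).max() < 1e-8


class TestSimulate:
    def test_single_cycle_qualitative_trajectory(self):
        proto = single_cycle_square_wave(offset_duration=900)
        res = simulate(HR_CIRCUIT, SwitchSchedule.from_protocol(proto))
        i_peak = np.argmax(res.v_c1)
        assert res.times[i_peak] == pytest.approx(600.0, abs=1.5)
        assert res.v_c1[i_peak] == pytest.approx(55.11319, rel=5e-3)  # rising toward V
        assert res.t_recovery is not None
        # decays through offset, then drains in recovery
        assert res.v_c1[-1] < res.v_c1[i_peak] * 0.3
        assert (Mode.RECOVERY in set(res.mode))

    def test_zero_duration_onset_keeps_baseline(self):
        sched = SwitchSchedule(
            events=((0.0, Mode.RECOVERY), (240.0, Mode.ONSET), (240.0, Mode.OFFSET)),
            total_duration=600.0,
        )
        res = simulate(HR_CIRCUIT, sched)
        assert np.all(res.v_c1 == 0.0) and np.all(res.v_c2 == 0.0)

    def test_state_continuity_across_interval_training_switches(self):
        proto = interval_training(3)
        res = simulate(HR_CIRCUIT, SwitchSchedule.from_protocol(proto))
        assert res.max_switch_jump() == 0.0
        # and no sample-to-sample discontinuity beyond the smooth slew
        steps = np.abs(np.diff(res.v_c1))
        dt = np.diff(res.times)[0]
        max_slew = HR_CIRCUIT.V / min(HR_CIRCUIT.tau_onset, HR_CIRCUIT.tau_offset) * dt
        assert steps.max() <= max_slew

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            SwitchSchedule(events=((0.0, Mode.ONSET), (100.0, Mode.OFFSET), (50.0, Mode.ONSET)),
                           total_duration=200.0)

    def test_schedule_must_start_at_zero(self):
        with pytest.raises(ScheduleError):
            SwitchSchedule(events=((10.0, Mode.ONSET),), total_duration=100.0)

    def test_recovery_waits_for_cooldown_and_equilibrium(self):
        proto = interval_training(3, cooldown_duration=2000.0)
        sched = SwitchSchedule.from_protocol(proto)
        res = simulate(HR_CIRCUIT, sched)
        assert res.t_recovery is not None
        assert res.t_recovery >= sched.recovery_not_before
        i = int(np.searchsorted(res.times, res.t_recovery)) - 1
        gap = abs(res.v_c1[i] - res.v_c2[i])
        assert gap <= 1.05e-3 * HR_CIRCUIT.V + 0.05  # just crossed tolerance


class TestCoefficientMapping:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_inversion_identity(self, seed):
        rng = np.random.default_rng(seed)
        k_on, t_on, k_off, t_off = random_feasible_characteristics(rng)
        du = rng.uniform(1.0, 8.0)
        r2 = rng.uniform(10.0, 500.0)
        p = circuit_from_characteristics(k_on, t_on, k_off, t_off, r2=r2, step_amplitude=du)
        ch = characteristics_from_circuit(p, step_amplitude=du)
        assert ch.k_on == pytest.approx(k_on, rel=1e-12)
        assert ch.t_on == pytest.approx(t_on, rel=1e-12)
        assert ch.k_off == pytest.approx(k_off, rel=1e-12)
        assert ch.t_off == pytest.approx(t_off, rel=1e-12)
        assert p.R2 == r2

    def test_scaling_supply_scales_gains_not_time_constants(self):
        p = HR_CIRCUIT
        doubled = CircuitParams(V=2 * p.V, R1=p.R1, R2=p.R2, R3=p.R3, C1=p.C1, C2=p.C2)
        a = characteristics_from_circuit(p)
        b = characteristics_from_circuit(doubled)
        assert b.k_on == pytest.approx(2 * a.k_on) and b.k_off == pytest.approx(2 * a.k_off)
        assert b.t_on == a.t_on and b.t_off == a.t_off

    def test_onset_time_constant_matches_efolding_of_simulated_trace(self):
        p = HR_CIRCUIT
        ch = characteristics_from_circuit(p)
        s = onset_evolve(CircuitState(0.0, 0.0, Mode.ONSET), p, ch.t_on)
        assert s.v_c1 == pytest.approx(p.V * (1 - np.exp(-1.0)), rel=1e-12)

    def test_gain_degeneracy_flagged(self):
        with pytest.raises(InfeasibleCircuitError):
            circuit_from_characteristics(13.35, 60.6, 13.35, 88.99)  # k_off == k_on
        with pytest.raises(InfeasibleCircuitError):
            circuit_from_characteristics(13.35, 60.6, 13.0, 20.0)  # t_off too small

    @pytest.mark.parametrize(
        "population", [HR_POPULATION, VO2_POPULATION], ids=["hr", "vo2"]
    )
    def test_population_means_reproduce_onset_offset_asymmetry(self, population):
        """Circuits built from the cohort means must re-fit with T_off > T_on
        and K_off < K_on, the empirically observed asymmetry."""
        from cardiorc import ExerciseProtocol, ProtocolSegment

        p = circuit_from_characteristics(
            population.k_on_mean,
            population.t_on_mean,
            population.k_off_mean,
            population.t_off_mean,
        )
        proto = ExerciseProtocol(
            (
                ProtocolSegment("warmup", 5.0, 240.0),
                ProtocolSegment("onset", 9.0, 900.0),
                ProtocolSegment("offset", 5.0, 420.0),
            )
        )
        res = simulate(p, SwitchSchedule.from_protocol(proto))
        on_fit, off_fit = identify_onset_offset(res.output_series(), proto)
        assert off_fit.T > on_fit.T
        assert off_fit.K < on_fit.K


class TestToPhysiology:
    def test_baseline_addition_and_additivity(self):
        proto = single_cycle_square_wave()
        res = simulate(HR_CIRCUIT, SwitchSchedule.from_protocol(proto))
        base80 = to_physiology(res, 80.0)
        base50 = to_physiology(res, 50.0)
        assert np.allclose(base80.values - base50.values, 30.0)
        assert base80.values[0] == 80.0  # zero v_c1 at start

    def test_long_onset_plateau_reaches_supply_plus_baseline(self):
        sched = SwitchSchedule(
            events=((0.0, Mode.RECOVERY), (10.0, Mode.ONSET)),
            total_duration=10.0 + 30 * VO2_CIRCUIT.tau_onset,
        )
        res = simulate(VO2_CIRCUIT, sched)
        out = to_physiology(res, 900.0)
        assert out.values[-1] == pytest.approx(900.0 + 1319.0, rel=1e-9)


class TestParamValidation:
    def test_nonpositive_components_rejected(self):
        with pytest.raises(InfeasibleCircuitError):
            CircuitParams(V=10, R1=0, R2=1, R3=1e4, C1=1, C2=1)

    def test_small_r3_warns(self):
        with pytest.warns(UserWarning):
            CircuitParams(V=10, R1=100, R2=100, R3=50, C1=1, C2=1)

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "p.json"
        HR_CIRCUIT.to_json(path)
        assert CircuitParams.from_json(path) == HR_CIRCUIT
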