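"""Engine contracts: transitions, tunnels, absorption, pairing, and the
agreement between the scalar reference path and the vectorized cohort path."""

import math

import numpy as np
import pytest

from folicsim import economics
from folicsim.engine import (
    ALLOWED_TRANSITIONS,
    HealthState,
    SimulationSettings,
    run_arm,
    run_cohort,
    simulate_individual,
    step,
    uniform_matrix,
)
from folicsim.synthetic_population import Cohort, generate_cohort


@pytest.fixture()
def one_patient(params):
    return generate_cohort(1, params, seed=5).patients()[0]


class TestStep:
    def test_null_world_stays_pre_cvd(self, null_params, one_patient):
        for u in (0.0, 0.5, 0.999):
            res = step(one_patient, HealthState.PRE_CVD, 0, null_params, "control", u)
            assert res.next_state is HealthState.PRE_CVD
            assert res.event is None

    def test_tunnel_exit_without_events(self, null_params, one_patient):
        res = step(one_patient, HealthState.STROKE_Y1, 1, null_params, "folic", 0.37)
        assert res.next_state is HealthState.POST_STROKE
        res = step(one_patient, HealthState.CHD_Y1, 1, null_params, "folic", 0.37)
        assert res.next_state is HealthState.POST_CHD

    def test_forced_noncvd_death(self, null_params, one_patient):
        p = null_params.copy()
        n = p.life_table.age_max - p.life_table.age_min + 1
        p.life_table.qx_male = [1.0] * n
        p.life_table.qx_female = [1.0] * n
        res = step(one_patient, HealthState.PRE_CVD, 0, p, "control", 0.9999)
        assert res.next_state is HealthState.DEAD
        assert res.event == "noncvd_death"

    def test_forced_relapse_is_recurrent(self, null_params, one_patient):
        p = null_params.copy()
        p.rates.stroke_relapse_year1 = 1.0
        res = step(
            one_patient, HealthState.STROKE_Y1, 1, p, "control", 0.5, had_stroke=True
        )
        assert res.next_state is HealthState.STROKE_Y1
        assert res.event == "stroke"
        assert res.recurrent is True
        assert res.subtype in ("ischemic", "hemorrhagic")

    def test_dead_state_rejected(self, params, one_patient):
        with pytest.raises(ValueError):
            step(one_patient, HealthState.DEAD, 0, params, "control", 0.5)

    def test_determinism(self, params, one_patient):
        a = step(one_patient, HealthState.PRE_CVD, 3, params, "folic", 0.123456)
        b = step(one_patient, HealthState.PRE_CVD, 3, params, "folic", 0.123456)
        assert a == b


class TestSimulateIndividual:
    def test_horizon_censoring_with_zero_mortality(self, null_params, one_patient):
        settings = SimulationSettings(seed=1, max_age=int(one_patient.age) + 5)
        traj = simulate_individual(
            one_patient, "control", null_params, settings,
            uniforms=np.full(10, 0.5),
        )
        assert traj.terminal_cause == "censored_at_horizon"
        assert len(traj.records) <= 5
        assert all(r.state is HealthState.PRE_CVD for r in traj.records)

    def test_paired_null_effect_trajectories_identical(self, equal_arm_params, params):
        cohort = generate_cohort(50, equal_arm_params, seed=8)
        settings = SimulationSettings(seed=8)
        U = uniform_matrix(50, 60, 8)
        for i, patient in enumerate(cohort.patients()):
            a = simulate_individual(patient, "folic", equal_arm_params, settings, uniforms=U[i])
            b = simulate_individual(patient, "control", equal_arm_params, settings, uniforms=U[i])
            assert a == b

    def test_near_certain_stroke_fires_first_cycle(self, params, one_patient):
        p = params.copy()
        p.weibull.scale = 10.0  # annual probability ~ 1 in year 1
        traj = simulate_individual(
            one_patient, "control", p, SimulationSettings(seed=1), uniforms=np.full(60, 0.3)
        )
        assert traj.records[0].event == "stroke"

    def test_graph_closure_tunnels_and_absorption(self, params):
        """Every observed transition lies in the allowed graph; tunnel states
        never persist without a relapse event; nothing follows death."""
        cohort = generate_cohort(150, params, seed=21)
        settings = SimulationSettings(seed=21)
        U = uniform_matrix(150, 70, 21)
        p = params.copy()
        p.rates.stroke_relapse_year1 = 0.5  # exercise relapse paths
        p.rates.chd_relapse_year1 = 0.5
        p.weibull.scale *= 10
        saw_relapse = False
        for i, patient in enumerate(cohort.patients()):
            traj = simulate_individual(patient, "folic", p, settings, uniforms=U[i])
            states = [r.state for r in traj.records]
            assert HealthState.DEAD not in states  # records cover alive cycles only
            for prev, nxt, rec in zip(states, states[1:], traj.records):
                assert nxt in ALLOWED_TRANSITIONS[prev], (prev, nxt)
                if prev is nxt and prev in (HealthState.STROKE_Y1, HealthState.CHD_Y1):
                    assert rec.event in ("stroke", "chd"), "tunnel persisted without relapse"
                    saw_relapse = True
            ages = [r.age for r in traj.records]
            assert all(abs(b - a - 1.0) < 1e-9 for a, b in zip(ages, ages[1:]))
        assert saw_relapse


class TestRunCohort:
    def test_empty_cohort_rejected(self, params):
        empty = generate_cohort(1, params, seed=1)
        empty.table = empty.table.iloc[:0]
        with pytest.raises(ValueError):
            run_cohort(empty, params, SimulationSettings(seed=1))

    def test_identical_params_paired_gives_exact_zero_increments(self, equal_arm_params):
        cohort = generate_cohort(2000, equal_arm_params, seed=4)
        folic, control = run_cohort(cohort, equal_arm_params, SimulationSettings(seed=4))
        assert folic.cost == control.cost
        assert folic.qalys == control.qalys
        assert folic.life_years == control.life_years
        assert folic.event_counts == control.event_counts

    def test_weaker_benefit_never_reduces_folic_strokes(self, params):
        cohort = generate_cohort(5000, params, seed=6)
        settings = SimulationSettings(seed=6)
        strokes = []
        for hr in (0.68, 0.79, 0.93, 1.0):
            p = params.copy()
            p.effect.hazard_ratio = hr
            p.effect.ci_low = min(p.effect.ci_low, hr)
            p.effect.ci_high = max(p.effect.ci_high, hr)
            folic, _ = run_cohort(cohort, p.validate(), settings)
            strokes.append(folic.event_counts["first_stroke"])
        assert strokes == sorted(strokes)

    def test_scalar_and_vector_paths_agree(self, params):
        n = 200
        cohort = generate_cohort(n, params, seed=7)
        settings = SimulationSettings(n_patients=n, seed=7)
        res = run_arm(cohort, params, settings, "folic")
        max_age = settings.resolve_max_age(params)
        t_max = max(int(math.ceil(max_age - cohort.table["age"].min())), 1)
        U = uniform_matrix(n, t_max, 7)
        for i, patient in enumerate(cohort.patients()):
            traj = simulate_individual(patient, "folic", params, settings, uniforms=U[i])
            acc = economics.accumulate(traj, params, "folic")
            assert acc["cost"] == pytest.approx(res.per_patient["cost"][i], rel=1e-9, abs=1e-9)
            assert acc["qalys"] == pytest.approx(res.per_patient["qalys"][i], rel=1e-9, abs=1e-12)
            assert acc["life_years"] == pytest.approx(
                res.per_patient["life_years"][i], rel=1e-9, abs=1e-12
            )

    def test_unpaired_arms_use_distinct_streams(self, equal_arm_params):
        cohort = generate_cohort(2000, equal_arm_params, seed=4)
        settings = SimulationSettings(seed=4, paired_arms=False)
        folic, control = run_cohort(cohort, equal_arm_params, settings)
        assert folic.cost != control.cost  # same law, different noise

    def test_half_cycle_correction_reduces_life_years(self, params):
        cohort = generate_cohort(2000, params, seed=9)
        full, _ = run_cohort(cohort, params, SimulationSettings(seed=9))
        half, _ = run_cohort(cohort, params, SimulationSettings(seed=9, half_cycle=True))
        assert half.life_years < full.life_years
        assert half.cost == full.cost  # costs still accrue on whole cycles

    def test_in_trial_horizon_cap(self, params):
        cohort = generate_cohort(500, params, seed=3)
        folic, _ = run_cohort(cohort, params, SimulationSettings(seed=3, max_years=5))
        assert folic.life_years_undiscounted <= 5.0
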