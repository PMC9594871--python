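"""Cost/utility attachment and discounted accumulation, against arithmetic oracles."""

import math

import numpy as np
import pytest

from folicsim import economics
from folicsim.economics import (
    accumulate,
    annual_drug_cost,
    concomitant_annual_cost,
    discount_factor,
    event_cost,
    post_stroke_annual_cost,
    study_drug_annual_cost,
    utility_for,
)
from folicsim.engine import CycleRecord, HealthState, SimulationSettings, Trajectory, run_arm, run_cohort
from folicsim.synthetic_population import generate_cohort


class TestDiscountFactor:
    def test_no_discounting(self):
        for year in (0, 1, 40):
            assert discount_factor(year, 0.0) == 1.0

    def test_present_value_year_zero(self):
        for rate in (0.0, 0.05, 0.08):
            assert discount_factor(0, rate) == 1.0

    def test_closed_form(self):
        assert discount_factor(3, 0.05) == pytest.approx(1 / 1.05**3, rel=1e-15)
        assert discount_factor(3, 0.05) == pytest.approx(0.863838, abs=5e-7)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestDrugCosts:
    def test_folic_arm_table_arithmetic(self, params):
        # 0.74/day x 365 x 0.692 adherence
        assert study_drug_annual_cost("folic", params) == pytest.approx(
            0.74 * 365 * 0.692, rel=1e-12
        )
        assert study_drug_annual_cost("folic", params) == pytest.approx(186.91, abs=0.01)

    def test_zero_adherence_leaves_only_concomitants(self, params):
        p = params.copy()
        p.behavior.adherence_enalapril = 0.0
        assert study_drug_annual_cost("control", p) == 0.0
        assert annual_drug_cost("control", p) == concomitant_annual_cost(p)

    def test_concomitant_cost_symmetric_across_arms(self, params):
        assert concomitant_annual_cost(params) == pytest.approx(
            annual_drug_cost("folic", params) - study_drug_annual_cost("folic", params)
        )
        # calibrated near the in-trial average of ~$16.7/yr
        assert concomitant_annual_cost(params) == pytest.approx(16.7, abs=0.5)

    def test_unknown_arm_rejected(self, params):
        with pytest.raises(ValueError):
            study_drug_annual_cost("placebo", params)


class TestEventAndSequelaCosts:
    def test_printed_30_day_costs(self, params):
        assert event_cost("ischemic", params.costs) == 1529.18
        assert event_cost("hemorrhagic", params.costs) == 3207.55
        assert event_cost("chd", params.costs) == 4696.39

    def test_unknown_event_rejected(self, params):
        with pytest.raises(ValueError):
            event_cost("aneurysm", params.costs)

    def test_no_sequelae_no_cost(self, params):
        behav = params.behavior.__class__(disability_rate=0.0, rehabilitation_rate=0.0)
        assert post_stroke_annual_cost(1, behav, params.costs) == 0.0
        assert post_stroke_annual_cost(5, behav, params.costs) == 0.0

    def test_full_disability_home_care_arithmetic(self, params):
        behav = params.behavior.__class__(disability_rate=1.0, rehabilitation_rate=0.0)
        assert post_stroke_annual_cost(2, behav, params.costs) == pytest.approx(
            12 * 465.12, rel=1e-12
        )  # = 5581.44

    def test_default_expectation_matches_spreadsheet_oracle(self, params):
        c, b = params.costs, params.behavior
        for year, months in ((1, c.rehab_months_year1), (3, c.rehab_months_later)):
            expected = b.rehabilitation_rate * (
                months["training"] * c.rehab_monthly["training"]
                + months["checking"] * c.rehab_monthly["checking"]
            ) + b.disability_rate * c.home_care_months * c.rehab_monthly["home_care"]
            assert post_stroke_annual_cost(year, b, c) == pytest.approx(expected, rel=1e-12)


class TestUtilities:
    @pytest.mark.parametrize(
        "state,recurrent,expected",
        [
            ("pre_cvd", False, 0.90),
            ("stroke_y1", False, 0.76),
            ("stroke_y1", True, 0.30),
            ("post_stroke", False, 0.79),
            ("post_stroke", True, 0.33),
            ("chd_y1", False, 0.77),
            ("chd_y1", True, 0.64),
            ("post_chd", False, 0.89),
            ("post_chd", True, 0.76),
            ("dead", False, 0.0),
        ],
    )
    def test_state_utilities(self, params, state, recurrent, expected):
        assert utility_for(state, 1, recurrent, params.utilities) == expected

    def test_unknown_state_rejected(self, params):
        with pytest.raises(ValueError):
            utility_for("zombie", 1, False, params.utilities)


class TestAccumulate:
    def _record(self, cycle, state, ys=0, recurrent=False, subtype=None):
        return CycleRecord(
            cycle=cycle, age=60 + cycle, state=state, years_since_event=ys,
            recurrent_stroke=recurrent, recurrent_chd=recurrent, subtype=subtype,
        )

    def test_single_healthy_cycle_no_discounting(self, params):
        p = params.copy()
        p.econ.discount_rate = 0.0
        traj = Trajectory(patient_id=0, records=[self._record(0, HealthState.PRE_CVD)])
        acc = accumulate(traj, p, "control")
        assert acc["life_years"] == 1.0
        assert acc["qalys"] == 0.90
        assert acc["cost"] == pytest.approx(annual_drug_cost("control", p))

    def test_three_cycle_trajectory_matches_hand_computed_sums(self, params):
        """pre-CVD year, ischemic-stroke year, post-stroke year at 5%/yr."""
        traj = Trajectory(
            patient_id=0,
            records=[
                self._record(0, HealthState.PRE_CVD),
                self._record(1, HealthState.STROKE_Y1, ys=1, subtype="ischemic"),
                self._record(2, HealthState.POST_STROKE, ys=2),
            ],
        )
        acc = accumulate(traj, params, "folic")
        d = [1 / 1.05**t for t in range(3)]
        exp_cost = (
            d[0] * annual_drug_cost("folic", params)
            + d[1] * (1529.18 + post_stroke_annual_cost(1, params.behavior, params.costs))
            + d[2] * post_stroke_annual_cost(2, params.behavior, params.costs)
        )
        exp_qaly = d[0] * 0.90 + d[1] * 0.76 + d[2] * 0.79
        assert acc["cost"] == pytest.approx(exp_cost, rel=1e-12)
        assert acc["qalys"] == pytest.approx(exp_qaly, rel=1e-12)
        assert acc["life_years"] == pytest.approx(sum(d), rel=1e-12)
        assert acc["life_years_undiscounted"] == 3.0

    def test_additive_over_concatenated_segments(self, params):
        recs = [
            self._record(0, HealthState.PRE_CVD),
            self._record(1, HealthState.PRE_CVD),
            self._record(2, HealthState.CHD_Y1, ys=1),
            self._record(3, HealthState.POST_CHD, ys=2),
        ]
        whole = accumulate(Trajectory(0, recs), params, "control")
        part_a = accumulate(Trajectory(0, recs[:2]), params, "control")
        part_b = accumulate(Trajectory(0, recs[2:]), params, "control")
        for key in ("cost", "qalys", "life_years"):
            assert whole[key] == pytest.approx(part_a[key] + part_b[key], rel=1e-12)

    def test_unit_utilities_make_qalys_equal_life_years(self, params):
        p = params.copy()
        for name in vars(p.utilities):
            setattr(p.utilities, name, 1.0)
        cohort = generate_cohort(300, p, seed=15)
        res = run_arm(cohort, p, SimulationSettings(seed=15), "control")
        np.testing.assert_allclose(
            res.per_patient["qalys"], res.per_patient["life_years"], rtol=1e-12
        )


@pytest.fixture()
def result(params):
    cohort = generate_cohort(2000, params, seed=31)
    return run_arm(cohort, params, SimulationSettings(seed=31), "folic")


class TestArmResultInvariants:

    def test_total_cost_equals_category_sum(self, result):
        assert sum(result.cost_by_category.values()) == pytest.approx(
            result.cost, rel=1e-9
        )

    def test_discounted_not_exceeding_undiscounted(self, result):
        assert result.cost <= result.cost_undiscounted
        assert result.life_years <= result.life_years_undiscounted
        assert result.qalys <= result.qalys_undiscounted

    def test_discount_monotonicity_cohort_wide(self, params):
        cohort = generate_cohort(2000, params, seed=32)
        totals = []
        for rate in (0.0, 0.03, 0.05, 0.08):
            p = params.copy()
            p.econ.discount_rate = rate
            res = run_arm(cohort, p, SimulationSettings(seed=32), "control")
            totals.append((res.cost, res.qalys, res.life_years))
        for a, b in zip(totals, totals[1:]):
            assert all(x >= y for x, y in zip(a, b))
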