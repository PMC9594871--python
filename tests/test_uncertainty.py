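"""Tornado, PSA/CEAC, scenarios, HR threshold search, and subgroup batch runs."""

import math

import numpy as np
import pytest

from folicsim import cea
from folicsim.engine import SimulationSettings, run_cohort
from folicsim.parameters import SubgroupSpec, UncertainParameter, to_dict
from folicsim.synthetic_population import generate_cohort
from folicsim.uncertainty import (
    SCENARIOS,
    ScenarioSpec,
    apply_scenario,
    find_hr_threshold,
    one_way_sa,
    run_psa,
    run_subgroups,
)

SMALL = dict(n_patients=3000, seed=12)


class TestScenarios:
    def test_half_price_multiplies_folic_price_only(self, params):
        p = apply_scenario(params, SCENARIOS["half_price"])
        assert p.costs.drug_unit_prices["enalapril_folic"] == pytest.approx(0.37)
        assert p.costs.drug_unit_prices["enalapril"] == 0.09
        assert params.costs.drug_unit_prices["enalapril_folic"] == 0.74  # input untouched

    def test_identity_scenario_is_a_no_op(self, params):
        p = apply_scenario(params, ScenarioSpec("noop"))
        assert to_dict(p) == to_dict(params)

    def test_benefit_cap_silences_hr_after_cutoff(self, params):
        from folicsim.risk_models import apply_hazard_ratio

        p = apply_scenario(params, SCENARIOS["benefit_5y"])
        assert apply_hazard_ratio(0.05, p.effect, 4).value < 0.05
        assert apply_hazard_ratio(0.05, p.effect, 5).value == 0.05

    def test_half_price_scenario_locality_under_crn(self, params):
        """Price changes leave trajectories untouched: the QALY increment is
        bit-identical and the cost increment shifts by exactly the discounted
        folic-arm drug saving."""
        settings = SimulationSettings(**SMALL)
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
        f0, c0 = run_cohort(cohort, params, settings)
        ph = apply_scenario(params, SCENARIOS["half_price"])
        f1, c1 = run_cohort(cohort, ph, settings)
        assert (f1.qalys - c1.qalys) == (f0.qalys - c0.qalys)
        assert (f1.life_years - c1.life_years) == (f0.life_years - c0.life_years)
        shift = (f0.cost - c0.cost) - (f1.cost - c1.cost)
        assert shift == pytest.approx(0.5 * f0.cost_by_category["drug"], rel=1e-9)

    def test_half_price_scenario_rescales_its_uncertainty_spec(self, params):
        """PSA draws inside the scenario must vary around the discounted
        price, not silently restore the original one."""
        p = apply_scenario(params, SCENARIOS["half_price"])
        u = p.uncertainty["costs.drug_unit_prices.enalapril_folic"]
        assert u.base == pytest.approx(0.37)
        assert u.high <= 0.6
        base_psa = run_psa(params, SimulationSettings(seed=19), n_outer=20, n_inner=400)
        half_psa = run_psa(p, SimulationSettings(seed=19), n_outer=20, n_inner=400)
        assert (half_psa.delta_cost < base_psa.delta_cost).all()
        np.testing.assert_array_equal(half_psa.delta_effect, base_psa.delta_effect)

    def test_shorter_benefit_raises_icer(self, params):
        settings = SimulationSettings(**SMALL)
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
        icers = {}
        for name in ("base", "benefit_10y", "benefit_5y"):
            f, c = run_cohort(cohort, apply_scenario(params, SCENARIOS[name]), settings)
            icers[name] = cea.icer(f, c).icer
        assert icers["base"] < icers["benefit_10y"] < icers["benefit_5y"]


class TestOneWaySA:
    def test_zero_width_range_gives_zero_bar(self, params):
        p = params.copy()
        p.uncertainty["utilities.pre_cvd"] = UncertainParameter(
            "utilities.pre_cvd", "beta", 0.90, 0.90, 0.90
        )
        entries = one_way_sa(p, SimulationSettings(**SMALL), parameters=["utilities.pre_cvd"])
        assert entries[0].width == 0.0
        assert entries[0].icer_low == entries[0].icer_high

    def test_weaker_hr_bound_raises_icer_and_runs_are_reproducible(self, params):
        settings = SimulationSettings(**SMALL)
        entries = one_way_sa(
            params, settings, parameters=["effect.hazard_ratio", "econ.discount_rate"]
        )
        again = one_way_sa(
            params, settings, parameters=["effect.hazard_ratio", "econ.discount_rate"]
        )
        assert [(e.parameter, e.icer_low, e.icer_high) for e in entries] == [
            (e.parameter, e.icer_low, e.icer_high) for e in again
        ]
        hr_entry = next(e for e in entries if e.parameter == "effect.hazard_ratio")
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
        f, c = run_cohort(cohort, params, settings)
        base_icer = cea.icer(f, c).icer
        assert hr_entry.icer_high > base_icer > hr_entry.icer_low
        assert entries[0].width >= entries[1].width  # sorted by bar width

    def test_discount_rate_bounds_both_present(self, params):
        entries = one_way_sa(params, SimulationSettings(**SMALL), parameters=["econ.discount_rate"])
        e = entries[0]
        assert (e.low_input, e.high_input) == (0.0, 0.08)
        assert math.isfinite(e.icer_low) and math.isfinite(e.icer_high)


class TestPSA:
    def test_degenerate_psa_is_a_step_function_at_the_base_icer(self, params):
        p = params.copy()
        for path, u in p.uncertainty.items():
            p.uncertainty[path] = UncertainParameter(path, "fixed", u.base, u.low, u.high)
        out = run_psa(p, SimulationSettings(seed=13), n_outer=5, n_inner=500)
        assert np.ptp(out.delta_cost) == 0.0
        assert np.ptp(out.delta_effect) == 0.0
        base_icer = out.delta_cost[0] / out.delta_effect[0]
        expected = (out.wtp_grid > base_icer).astype(float)
        # at wtp == icer exactly, NMB is 0 (not > 0): step at the ICER
        np.testing.assert_array_equal(out.ceac, expected)

    def test_ceac_boundary_and_monotonicity(self, params):
        out = run_psa(params, SimulationSettings(seed=14), n_outer=40, n_inner=400)
        assert out.ceac[0] == pytest.approx(float((out.delta_cost < 0).mean()))
        if (out.delta_effect > 0).all():
            assert (np.diff(out.ceac) >= -1e-12).all()
        assert out.acceptance_at_gdp[1] <= out.acceptance_at_gdp[2] <= out.acceptance_at_gdp[3]

    def test_reproducible_given_seed(self, params):
        a = run_psa(params, SimulationSettings(seed=15), n_outer=5, n_inner=300)
        b = run_psa(params, SimulationSettings(seed=15), n_outer=5, n_inner=300)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_effect, b.delta_effect)

    def test_invalid_replicate_counts_rejected(self, params):
        with pytest.raises(ValueError):
            run_psa(params, SimulationSettings(seed=1), n_outer=0, n_inner=10)


class TestHRThreshold:
    def test_threshold_consistent_with_base_icer(self, params):
        """Searching with WTP set to the base-case ICER must return ~ the base HR."""
        settings = SimulationSettings(n_patients=8000, seed=16)
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
        f, c = run_cohort(cohort, params, settings)
        base_icer = cea.icer(f, c).icer
        hr = find_hr_threshold(params, settings, wtp=base_icer, tol=2e-3)
        assert hr == pytest.approx(params.effect.hazard_ratio, abs=5e-3)

    def test_threshold_increases_with_wtp(self, params):
        settings = SimulationSettings(n_patients=6000, seed=17)
        hrs = [
            find_hr_threshold(params, settings, wtp=w, tol=2e-3)
            for w in (20_000.0, 37_663.0, 60_000.0)
        ]
        assert hrs == sorted(hrs)
        assert all(params.effect.ci_low < h < 1.0 for h in hrs)

    def test_missing_bracket_rejected(self, params):
        with pytest.raises(ValueError):
            find_hr_threshold(params, SimulationSettings(n_patients=2000, seed=18), wtp=1.0)


class TestSubgroups:
    def test_identity_overrides_reproduce_all_patients_run(self, params):
        settings = SimulationSettings(**SMALL)
        spec = SubgroupSpec(name="everyone", predicate="age >= 0")
        res = run_subgroups([spec], params, settings)[0]
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
        f, c = run_cohort(cohort, params, settings)
        expected = cea.icer(f, c)
        assert res.ce.delta_cost == expected.delta_cost
        assert res.ce.delta_effect == expected.delta_effect

    def test_partition_conserves_members_and_empty_flagged(self, params):
        settings = SimulationSettings(**SMALL)
        specs = [
            SubgroupSpec(name="male", predicate="sex == 'male'"),
            SubgroupSpec(name="female", predicate="sex == 'female'"),
            SubgroupSpec(name="nobody", predicate="age > 500"),
        ]
        results = run_subgroups(specs, params, settings)
        assert results[0].n_members + results[1].n_members == SMALL["n_patients"]
        assert results[2].skipped and results[2].reason == "empty subgroup"

    def test_subgroup_icer_monotone_in_hazard_ratio(self, params):
        settings = SimulationSettings(**SMALL)
        icers = []
        for hr in (0.70, 0.85):
            spec = SubgroupSpec(name=f"male_hr{hr}", predicate="sex == 'male'", hazard_ratio=hr)
            res = run_subgroups([spec], params, settings)[0]
            icers.append(res.ce.icer)
        assert icers[0] < icers[1]

    def test_subgroup_weibull_override_applies(self, params):
        from folicsim.parameters import WeibullIncidence

        settings = SimulationSettings(**SMALL)
        hot = SubgroupSpec(
            name="high_risk", predicate="age >= 0",
            weibull=WeibullIncidence(scale=params.weibull.scale * 3, shape=1.0),
        )
        base = run_subgroups([SubgroupSpec(name="all", predicate="age >= 0")], params, settings)[0]
        risky = run_subgroups([hot], params, settings)[0]
        assert risky.ce.delta_effect > base.ce.delta_effect  # more strokes to avert
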