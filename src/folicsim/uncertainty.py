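"""Sensitivity, scenario, and subgroup machinery.

* One-way deterministic sensitivity analysis (tornado): each uncertain
  parameter is set to its lower and upper bound in turn, everything else at
  base, under common random numbers, and the resulting ICERs span the bar.
* Probabilistic sensitivity analysis: each replicate jointly re-draws all
  uncertain parameters from their distributions, simulates a paired cohort,
  and records the incremental cost and effect; the cost-effectiveness
  acceptability curve (CEAC) is the fraction of replicates with positive net
  monetary benefit at each willingness-to-pay value.
* Scenario engine: drug-price multipliers (the half-price patient-aid-program
  scenario) and treatment-benefit duration caps (5- and 10-year scenarios).
* Subgroup batch runs with per-subgroup Weibull/hazard-ratio overrides and
  refitted baseline distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import cea, economics
from .engine import SimulationSettings, run_cohort
from .parameters import (
    ParameterSet,
    SubgroupSpec,
    UncertainParameter,
    perturb,
    sample_psa_draw,
)
from .synthetic_population import Cohort, filter_subgroup, generate_cohort

__all__ = [
    "TornadoEntry",
    "PSAOutput",
    "ScenarioSpec",
    "SCENARIOS",
    "one_way_sa",
    "run_psa",
    "apply_scenario",
    "find_hr_threshold",
    "run_subgroups",
]

log = logging.getLogger(__name__)


def _base_case(
    params: ParameterSet, settings: SimulationSettings, cohort: Cohort | None = None
) -> tuple[economics.ArmResult, economics.ArmResult]:
    if cohort is None:
        cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
    return run_cohort(cohort, params, settings)


def _signed_ratio(folic: economics.ArmResult, control: economics.ArmResult, kind: str) -> float:
    """Raw delta-cost / delta-effect, used only for tornado bar geometry."""
    ce = cea.icer(folic, control, kind)
    if ce.icer is not None:
        return ce.icer
    if ce.delta_effect == 0:
        return math.inf if ce.delta_cost > 0 else -math.inf
    return ce.delta_cost / ce.delta_effect


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    icer_low: float  # ICER with the parameter at its lower bound
    icer_high: float  # ICER with the parameter at its upper bound

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def one_way_sa(
    params: ParameterSet,
    settings: SimulationSettings,
    specs: dict[str, UncertainParameter] | None = None,
    effect_kind: str = "qaly",
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: two runs per parameter at its bounds, CRN fixed.

    Entries come back sorted by descending bar width. Parameters without a
    usable range (low == high) produce zero-width bars; parameters lacking
    bounds entirely are skipped with a warning.
    """
    specs = params.uncertainty if specs is None else specs
    cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
    entries = []
    paths = parameters if parameters is not None else sorted(specs)
    for path in paths:
        u = specs[path]
        if not np.isfinite([u.low, u.high]).all():
            log.warning("one_way_sa: skipping %s (unbounded range)", path)
            continue
        icers = {}
        for bound_name, bound in (("low", u.low), ("high", u.high)):
            p_bound = perturb(params, {path: bound})
            folic, control = run_cohort(cohort, p_bound, settings)
            icers[bound_name] = _signed_ratio(folic, control, effect_kind)
        entries.append(
            TornadoEntry(
                parameter=path,
                low_input=u.low,
                high_input=u.high,
                icer_low=icers["low"],
                icer_high=icers["high"],
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Scenario engine
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """A named transform of the base case (price multiplier / benefit cap)."""

    name: str
    drug_price_multiplier: float = 1.0
    benefit_duration_years: float = math.inf
    effect_kind: str = "qaly"

    def validate(self) -> None:
        if self.drug_price_multiplier <= 0:
            raise ValueError("drug_price_multiplier must be > 0")
        if self.benefit_duration_years <= 0:
            raise ValueError("benefit_duration_years must be > 0")


SCENARIOS = {
    "base": ScenarioSpec("base"),
    "half_price": ScenarioSpec("half_price", drug_price_multiplier=0.5),
    "benefit_5y": ScenarioSpec("benefit_5y", benefit_duration_years=5.0),
    "benefit_10y": ScenarioSpec("benefit_10y", benefit_duration_years=10.0),
}


def apply_scenario(params: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return params with the scenario transforms applied (input untouched)."""
    scenario.validate()
    out = params.copy()
    m = scenario.drug_price_multiplier
    out.costs.drug_unit_prices["enalapril_folic"] *= m
    # keep the PSA/DSA spec consistent with the discounted price, otherwise
    # sensitivity draws would silently restore the original price
    u = out.uncertainty.get("costs.drug_unit_prices.enalapril_folic")
    if u is not None:
        u.base *= m
        u.low *= m
        u.high *= m
    out.effect.benefit_duration_years = scenario.benefit_duration_years
    return out.validate()


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAOutput:
    """Per-replicate increments plus the derived acceptability summaries."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    effect_kind: str
    wtp_grid: np.ndarray
    ceac: np.ndarray
    acceptance_at_gdp: dict[int, float]  # GDP multiple -> acceptance probability
    n_outer: int = 0
    n_inner: int = 0

    def acceptance_at(self, wtp: float) -> float:
        nmb = wtp * self.delta_effect - self.delta_cost
        return float((nmb > 0).mean())


def default_wtp_grid(gdp: float, n_points: int = 101, top_multiple: float = 5.0) -> np.ndarray:
    return np.linspace(0.0, top_multiple * gdp, n_points)


def run_psa(
    params: ParameterSet,
    settings: SimulationSettings,
    n_outer: int = 1000,
    n_inner: int = 2000,
    specs: dict[str, UncertainParameter] | None = None,
    wtp_grid: np.ndarray | None = None,
    effect_kind: str = "qaly",
) -> PSAOutput:
    """Monte-Carlo PSA: ``n_outer`` joint parameter draws, each simulated on a
    paired cohort of ``n_inner`` patients under common random numbers.

    One baseline cohort is generated once and reused across replicates, and
    the transition-uniform stream is also shared across replicates (common
    random numbers in every dimension), so replicates differ only through
    their parameter draws: parameter uncertainty is isolated from
    Monte-Carlo noise, and a fully degenerate specification yields identical
    replicates. The whole analysis is reproducible from the seed.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    specs = params.uncertainty if specs is None else specs
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(params.econ.gdp_per_capita)
    cohort = generate_cohort(n_inner, params, seed=settings.seed)
    root = np.random.SeedSequence(settings.seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    dc = np.empty(n_outer)
    de = np.empty(n_outer)
    for rep in range(n_outer):
        draws = sample_psa_draw(params, specs, rng_seed=draw_rng)
        p_rep = perturb(params, draws)
        rep_settings = SimulationSettings(
            n_patients=n_inner,
            seed=settings.seed,
            max_age=settings.max_age,
            paired_arms=True,
            half_cycle=settings.half_cycle,
            max_years=settings.max_years,
        )
        folic, control = run_cohort(cohort, p_rep, rep_settings)
        dc[rep] = folic.cost - control.cost
        de[rep] = (
            folic.qalys - control.qalys
            if effect_kind == "qaly"
            else folic.life_years - control.life_years
        )
    ceac = np.array([float(((w * de - dc) > 0).mean()) for w in wtp_grid])
    gdp = params.econ.gdp_per_capita
    acceptance = {
        k: float((((k * gdp) * de - dc) > 0).mean()) for k in (1, 2, 3)
    }
    return PSAOutput(
        delta_cost=dc,
        delta_effect=de,
        effect_kind=effect_kind,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        ceac=ceac,
        acceptance_at_gdp=acceptance,
        n_outer=n_outer,
        n_inner=n_inner,
    )


# ---------------------------------------------------------------------------
# Hazard-ratio threshold search
# ---------------------------------------------------------------------------


def find_hr_threshold(
    params: ParameterSet,
    settings: SimulationSettings,
    wtp: float | None = None,
    tol: float = 1e-3,
    effect_kind: str = "qaly",
) -> float:
    """Bisect for the hazard ratio at which the ICER crosses the WTP threshold.

    Evaluations use a fixed cohort and fixed uniform matrix (CRN), making
    ICER(HR) effectively deterministic and monotone so bisection is sound.
    Requires a bracket: ICER below ``wtp`` at the CI lower bound and above it
    at HR = 1 (where the ICER diverges as the effect vanishes).
    """
    wtp = params.econ.wtp_per_qaly if wtp is None else wtp
    cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)

    def icer_at(hr: float) -> float:
        p = params.copy()
        p.effect.hazard_ratio = hr  # bisection may probe beyond the printed CI
        p.effect.ci_low = min(p.effect.ci_low, hr)
        p.effect.ci_high = max(p.effect.ci_high, hr)
        folic, control = run_cohort(cohort, p.validate(), settings)
        return _signed_ratio(folic, control, effect_kind)

    lo, hi = params.effect.ci_low, 1.0 - 1e-9
    f_lo, f_hi = icer_at(lo), icer_at(hi)
    if not (f_lo < wtp < f_hi):
        raise ValueError(
            f"no bracket: ICER({lo:.3f})={f_lo:.1f}, ICER({hi:.3f})={f_hi:.1f}, wtp={wtp}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if icer_at(mid) < wtp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------


@dataclass
class SubgroupResult:
    name: str
    n_members: int
    ce: cea.CEResult | None
    classification: str | None
    acceptance_3gdp: float | None = None
    skipped: bool = False
    reason: str = ""


def _subgroup_params(params: ParameterSet, spec: SubgroupSpec) -> ParameterSet:
    out = params.copy()
    if spec.weibull is not None:
        out.weibull = spec.weibull
    if spec.hazard_ratio is not None:
        hr = spec.hazard_ratio
        out.effect.hazard_ratio = hr
        out.effect.ci_low = min(out.effect.ci_low, hr)
        out.effect.ci_high = max(out.effect.ci_high, hr)
    for key, value in spec.population.items():
        setattr(out.population, key, value)
    return out.validate()


def run_subgroups(
    specs: list[SubgroupSpec],
    params: ParameterSet,
    settings: SimulationSettings,
    psa_outer: int = 0,
    psa_inner: int | None = None,
    effect_kind: str = "qaly",
) -> list[SubgroupResult]:
    """Base-case (and optionally PSA) results per subgroup.

    Each subgroup filters the shared cohort by its predicate, applies its
    Weibull / hazard-ratio / population overrides, and runs with the same
    engine settings as the all-patients analysis. Empty subgroups are flagged
    and skipped. ``psa_outer > 0`` adds the acceptance probability at 3x GDP.
    """
    cohort = generate_cohort(settings.n_patients, params, seed=settings.seed)
    results = []
    for spec in specs:
        members = filter_subgroup(cohort, spec)
        if len(members) == 0:
            results.append(
                SubgroupResult(
                    name=spec.name, n_members=0, ce=None, classification=None,
                    skipped=True, reason="empty subgroup",
                )
            )
            continue
        p_sub = _subgroup_params(params, spec)
        folic, control = run_cohort(members, p_sub, settings)
        ce = cea.icer(folic, control, effect_kind)
        res = SubgroupResult(
            name=spec.name,
            n_members=len(members),
            ce=ce,
            classification=cea.classify(ce, p_sub.econ.gdp_per_capita),
        )
        if psa_outer > 0:
            psa = run_psa(
                p_sub,
                SimulationSettings(
                    n_patients=len(members), seed=settings.seed, max_age=settings.max_age
                ),
                n_outer=psa_outer,
                n_inner=psa_inner or len(members),
                effect_kind=effect_kind,
            )
            res.acceptance_3gdp = psa.acceptance_at_gdp[3]
        results.append(res)
    return results
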