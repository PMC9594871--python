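"""Costs, utilities, and discounted accumulation over simulated trajectories.

Costing follows the healthcare-sector perspective of the source analysis:

* pre-CVD years accrue study-drug cost (unit price/day x 365, adjusted by the
  arm's treatment adherence) plus concomitant-medication cost (per-class price
  x usage share, identical across arms by default);
* a CVD event charges the 30-day hospitalization cost of its type in the year
  it occurs, plus rest-of-first-year rehabilitation/disability costs for
  stroke;
* post-stroke years accrue an expected sequela cost
  ``rehabilitation_rate x (training + checking months x monthly rates)
  + disability_rate x home-care months x monthly rate``;
* post-CHD years accrue a configurable annual medication cost.

Study-drug costing stops at the first CVD event (in-trial costing stopped at
stroke); post-event medication is folded into the post-CVD costs. All
computation is in USD; RMB renderings use the fixed exchange rate.

Utilities are state utilities on [0, 1]; QALYs multiply time in state by the
utility, and life-years count alive cycles. Both are discounted per cycle at
the annual discount rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    BehaviorParameters,
    CostParameters,
    CONCOMITANT_CLASSES,
    ParameterSet,
    UtilityParameters,
)

__all__ = [
    "COST_CATEGORIES",
    "ArmResult",
    "discount_factor",
    "study_drug_annual_cost",
    "concomitant_annual_cost",
    "annual_drug_cost",
    "event_cost",
    "post_stroke_annual_cost",
    "post_chd_annual_cost",
    "utility_for",
    "accumulate",
]

COST_CATEGORIES = ("drug", "concomitant", "ischemic_stroke", "hemorrhagic_stroke", "chd", "post")

DAYS_PER_YEAR = 365.0


def discount_factor(year: int, rate: float) -> float:
    """Present-value factor ``1 / (1 + rate)**year`` for a whole-cycle payoff."""
    if year < 0:
        raise ValueError(f"year must be >= 0, got {year}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return 1.0 / (1.0 + rate) ** year


def study_drug_annual_cost(arm: str, params: ParameterSet) -> float:
    """Adherence-adjusted annual cost of the study drug for one arm."""
    if arm == "folic":
        price = params.costs.drug_unit_prices["enalapril_folic"]
        adherence = params.behavior.adherence_folic
    elif arm == "control":
        price = params.costs.drug_unit_prices["enalapril"]
        adherence = params.behavior.adherence_enalapril
    else:
        raise ValueError(f"unknown arm {arm!r}; expected 'folic' or 'control'")
    return price * DAYS_PER_YEAR * adherence


def concomitant_annual_cost(params: ParameterSet) -> float:
    """Annual concomitant-medication cost (price/day x 365 x usage share, summed)."""
    return sum(
        params.costs.drug_unit_prices[c] * DAYS_PER_YEAR * params.costs.concomitant_usage.get(c, 0.0)
        for c in CONCOMITANT_CLASSES
    )


def annual_drug_cost(arm: str, params: ParameterSet) -> float:
    """Total annual pre-CVD medication cost for one arm (study drug + concomitants)."""
    return study_drug_annual_cost(arm, params) + concomitant_annual_cost(params)


def event_cost(event: str, costs: CostParameters) -> float:
    """30-day hospitalization cost of a CVD event type."""
    key = {"ischemic": "ischemic_stroke", "hemorrhagic": "hemorrhagic_stroke", "chd": "chd"}.get(
        event, event
    )
    if key not in costs.event_costs_30d:
        raise ValueError(f"unknown event type {event!r}")
    return costs.event_costs_30d[key]


def post_stroke_annual_cost(
    years_since_stroke: int, behav: BehaviorParameters, costs: CostParameters
) -> float:
    """Expected rehabilitation + disability cost for one post-stroke year.

    ``years_since_stroke == 1`` is the rest of the event year (after the
    30-day hospitalization); later years use the maintenance month-counts.
    The rates enter as expectations rather than per-patient draws.
    """
    if years_since_stroke < 1:
        raise ValueError(f"years_since_stroke must be >= 1, got {years_since_stroke}")
    months = costs.rehab_months_year1 if years_since_stroke == 1 else costs.rehab_months_later
    rehab = behav.rehabilitation_rate * (
        months["training"] * costs.rehab_monthly["training"]
        + months["checking"] * costs.rehab_monthly["checking"]
    )
    disability = behav.disability_rate * costs.home_care_months * costs.rehab_monthly["home_care"]
    return rehab + disability


def post_chd_annual_cost(costs: CostParameters) -> float:
    """Annual post-CHD medication cost (config; the supplement's counts are unprinted)."""
    return costs.chd_annual_med_cost


_UTILITY_MAP = {
    ("pre_cvd", False): "pre_cvd",
    ("stroke_y1", False): "stroke_y1",
    ("stroke_y1", True): "stroke_recur_y1",
    ("post_stroke", False): "stroke_later",
    ("post_stroke", True): "stroke_recur_later",
    ("chd_y1", False): "chd_y1",
    ("chd_y1", True): "chd_recur_y1",
    ("post_chd", False): "chd_later",
    ("post_chd", True): "chd_recur_later",
}


def utility_for(
    state: str,
    years_since_event: int = 0,
    recurrent: bool = False,
    util: UtilityParameters | None = None,
) -> float:
    """Utility of a health state (``dead`` maps to 0 by definition of the scale)."""
    state = getattr(state, "value", state)
    if state == "dead":
        return 0.0
    if state == "pre_cvd":
        return (UtilityParameters() if util is None else util).pre_cvd
    util = UtilityParameters() if util is None else util
    try:
        return getattr(util, _UTILITY_MAP[(state, bool(recurrent))])
    except KeyError:
        raise ValueError(f"unknown health state {state!r}") from None


# ---------------------------------------------------------------------------
# Per-patient accumulation and per-arm aggregation
# ---------------------------------------------------------------------------


def accumulate(trajectory, params: ParameterSet, arm: str) -> dict:
    """Discounted and undiscounted economics of one trajectory.

    Payoffs accrue on whole cycles for the state occupied during each cycle
    (no half-cycle correction unless the engine applied it); cycle ``t`` is
    discounted by ``1/(1+r)**t``. Additive over cycles, so concatenating
    trajectory segments with correct cycle offsets sums exactly.
    """
    r = params.econ.discount_rate
    cost = {c: 0.0 for c in COST_CATEGORIES}
    cost_u = {c: 0.0 for c in COST_CATEGORIES}
    ly = qaly = ly_u = qaly_u = 0.0
    for rec in trajectory.records:
        state = getattr(rec.state, "value", rec.state)
        if state == "dead":
            continue
        d = discount_factor(rec.cycle, r)
        w = getattr(rec, "cycle_weight", 1.0)
        cyc = {c: 0.0 for c in COST_CATEGORIES}
        if state == "pre_cvd":
            cyc["drug"] = study_drug_annual_cost(arm, params)
            cyc["concomitant"] = concomitant_annual_cost(params)
        elif state == "stroke_y1":
            cat = "ischemic_stroke" if rec.subtype == "ischemic" else "hemorrhagic_stroke"
            cyc[cat] = params.costs.event_costs_30d[cat]
            cyc["post"] = post_stroke_annual_cost(1, params.behavior, params.costs)
        elif state == "chd_y1":
            cyc["chd"] = params.costs.event_costs_30d["chd"]
            cyc["post"] = post_chd_annual_cost(params.costs)
        elif state == "post_stroke":
            cyc["post"] = post_stroke_annual_cost(
                rec.years_since_event, params.behavior, params.costs
            )
        elif state == "post_chd":
            cyc["post"] = post_chd_annual_cost(params.costs)
        else:
            raise ValueError(f"unknown state {state!r} in trajectory")
        recurrent = rec.recurrent_stroke if "stroke" in state else rec.recurrent_chd
        u = utility_for(state, rec.years_since_event, recurrent, params.utilities)
        for c in COST_CATEGORIES:
            cost[c] += d * cyc[c]
            cost_u[c] += cyc[c]
        ly += d * w
        ly_u += w
        qaly += d * u * w
        qaly_u += u * w
    return {
        "cost": sum(cost.values()),
        "cost_by_category": cost,
        "cost_undiscounted": sum(cost_u.values()),
        "cost_by_category_undiscounted": cost_u,
        "life_years": ly,
        "life_years_undiscounted": ly_u,
        "qalys": qaly,
        "qalys_undiscounted": qaly_u,
    }


@dataclass
class ArmResult:
    """Per-arm aggregate economics over a simulated cohort.

    Means are per patient; ``se_*`` are Monte-Carlo standard errors of the
    means. ``per_patient`` holds the discounted per-patient totals (used for
    paired incremental statistics under common random numbers) and
    ``first_stroke_year`` the cycle of each patient's first stroke (-1 if
    none), used by the internal-validation machinery.
    """

    arm: str
    n: int
    cost: float
    cost_by_category: dict[str, float]
    life_years: float
    qalys: float
    cost_undiscounted: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    event_counts: dict[str, int]
    se_cost: float
    se_life_years: float
    se_qalys: float
    per_patient: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    first_stroke_year: np.ndarray | None = field(default=None, repr=False)
    pre_exit_year: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.cost_by_category.values())
        if abs(total - self.cost) > 1e-9 * max(1.0, abs(self.cost)):
            raise ValueError(
                f"cost categories ({total}) do not sum to total cost ({self.cost})"
            )

    def to_json_dict(self, exchange_rate: float | None = None) -> dict:
        out = {
            "arm": self.arm,
            "n": self.n,
            "cost_usd": self.cost,
            "cost_by_category_usd": dict(self.cost_by_category),
            "life_years": self.life_years,
            "qalys": self.qalys,
            "cost_undiscounted_usd": self.cost_undiscounted,
            "life_years_undiscounted": self.life_years_undiscounted,
            "qalys_undiscounted": self.qalys_undiscounted,
            "event_counts": {k: int(v) for k, v in self.event_counts.items()},
            "se": {
                "cost": self.se_cost,
                "life_years": self.se_life_years,
                "qalys": self.se_qalys,
            },
        }
        if exchange_rate:
            out["cost_rmb"] = self.cost * exchange_rate
        return out

    @classmethod
    def from_arrays(
        cls,
        arm: str,
        cost_by_cat: dict[str, np.ndarray],
        cost_by_cat_undisc: dict[str, np.ndarray],
        ly: np.ndarray,
        qaly: np.ndarray,
        ly_undisc: np.ndarray,
        qaly_undisc: np.ndarray,
        event_counts: dict[str, int],
        first_stroke_year: np.ndarray | None = None,
    ) -> "ArmResult":
        n = len(ly)
        cost = sum(cost_by_cat.values())
        cost_undisc = sum(cost_by_cat_undisc.values())
        sqrt_n = float(np.sqrt(n))
        return cls(
            arm=arm,
            n=n,
            cost=float(cost.mean()),
            cost_by_category={c: float(v.mean()) for c, v in cost_by_cat.items()},
            life_years=float(ly.mean()),
            qalys=float(qaly.mean()),
            cost_undiscounted=float(cost_undisc.mean()),
            life_years_undiscounted=float(ly_undisc.mean()),
            qalys_undiscounted=float(qaly_undisc.mean()),
            event_counts=event_counts,
            se_cost=float(cost.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
            se_life_years=float(ly.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
            se_qalys=float(qaly.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
            per_patient={"cost": cost, "qalys": qaly, "life_years": ly},
            first_stroke_year=first_stroke_year,
        )
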