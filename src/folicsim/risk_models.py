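"""Annual transition probabilities of the state-transition model.

Four sources feed the per-cycle transition probabilities:

* Weibull first-stroke incidence, converted to an annual probability between
  integer state-times as ``1 - exp(lambda * t**gamma - lambda * (t+1)**gamma)``,
  with the treatment hazard ratio applied by the proportional-hazards survival
  transform ``1 - (1 - p)**HR`` while the benefit lasts;
* the sex-specific 10-year CHD risk equation
  ``P = 1 - S10**exp(sum beta_i (x_i - M_i))`` annualized as
  ``1 - exp(ln(1 - P) / 10)``;
* fixed annual recurrence / cross-event / CVD-mortality rates by health state
  and year since the event;
* an age- and sex-indexed life table for non-CVD mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    CHDRiskModel,
    ConfigurationError,
    LifeTable,
    TransitionRates,
    TreatmentEffect,
    WeibullIncidence,
)

__all__ = [
    "AnnualProbability",
    "stroke_annual_prob",
    "apply_hazard_ratio",
    "chd_ten_year_risk",
    "annualize_ten_year",
    "noncvd_mortality",
    "post_event_probs",
]


@dataclass(frozen=True)
class AnnualProbability:
    """A one-cycle transition probability tagged with its source."""

    value: float
    source: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"annual probability {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def stroke_annual_prob(weibull: WeibullIncidence, state_year: int) -> AnnualProbability:
    """Annual first-stroke probability between state-times t and t+1.

    Equals ``1 - S(t+1)/S(t)`` for ``S(t) = exp(-lambda * t**gamma)``.
    """
    if state_year < 0:
        raise ValueError(f"state_year must be >= 0, got {state_year}")
    lam, gam = weibull.scale, weibull.shape
    t = float(state_year)
    value = -math.expm1(lam * t**gam - lam * (t + 1.0) ** gam)
    return AnnualProbability(value=value, source="weibull_stroke")


def apply_hazard_ratio(
    p: AnnualProbability | float, effect: TreatmentEffect, year: int
) -> AnnualProbability:
    """Scale an annual probability by the treatment hazard ratio.

    Under proportional hazards the per-cycle survival scales as a power:
    ``1 - (1 - p)**HR``. Beyond ``benefit_duration_years`` the probability is
    returned unchanged (scenario analyses cap the benefit at 5 or 10 years).
    """
    if year < 0:
        raise ValueError(f"year must be >= 0, got {year}")
    pv = float(p)
    if pv >= 1.0:
        raise ValueError("apply_hazard_ratio requires p in [0, 1)")
    if year < effect.benefit_duration_years:
        pv = -math.expm1(effect.hazard_ratio * math.log1p(-pv))
    return AnnualProbability(value=pv, source="weibull_stroke")


def _linear_predictor(patient, model: CHDRiskModel) -> float:
    lp = 0.0
    for factor, beta, mean in zip(model.factors, model.coefficients, model.reference_means):
        try:
            x = float(getattr(patient, factor))
        except AttributeError as exc:
            raise ConfigurationError(
                f"chd model factor {factor!r} not present on patient"
            ) from exc
        lp += beta * (x - mean)
    return lp


def chd_ten_year_risk(patient, model: CHDRiskModel) -> float:
    """10-year CHD risk ``P = 1 - S10**exp(f(x, M))`` for one patient.

    ``patient`` is anything exposing the model's factor names as attributes
    (binary factors as 0/1). The sex-specific model must be selected by the
    caller.
    """
    model.validate()
    lp = _linear_predictor(patient, model)
    p = -math.expm1(math.exp(lp) * math.log(model.baseline_survival_10y))
    return min(max(p, 0.0), 1.0)


def chd_ten_year_risk_vector(
    lp: np.ndarray, baseline_survival_10y: np.ndarray | float
) -> np.ndarray:
    """Vectorized 10-year CHD risk from precomputed linear predictors."""
    return -np.expm1(np.exp(lp) * np.log(baseline_survival_10y))


def annualize_ten_year(P: float) -> AnnualProbability:
    """Convert a 10-year risk to the annual probability with equal yearly hazard.

    ``a = 1 - exp(ln(1 - P)/10)``, so ``(1 - a)**10 = 1 - P`` exactly.
    """
    if not 0.0 <= P < 1.0:
        raise ValueError(f"10-year risk must be in [0, 1), got {P}")
    value = -math.expm1(math.log1p(-P) / 10.0)
    return AnnualProbability(value=value, source="chd_equation")


def noncvd_mortality(
    age: float, sex: str, table: LifeTable, clamp: bool = False
) -> AnnualProbability:
    """Annual non-CVD death probability from the life table.

    Ages outside the table raise ``LookupError`` unless ``clamp=True``, which
    clips to the nearest supported age (the engine clamps: simulated ages can
    exceed the youngest/oldest table rows by design).
    """
    return AnnualProbability(value=table.qx(age, sex, clamp=clamp), source="life_table")


_POST_STATES = ("stroke_y1", "post_stroke", "chd_y1", "post_chd")


def post_event_probs(
    state: str, years_since_event: int, rates: TransitionRates
) -> dict[str, AnnualProbability]:
    """Relapse, cross-event, and CVD-death probabilities for a post-event state.

    ``years_since_event`` is 1 in the event-year (tunnel) states and >= 2 in
    the post states, where it drives the declining stroke-relapse schedule.
    """
    if state not in _POST_STATES:
        raise ValueError(f"unknown post-event state {state!r}; expected one of {_POST_STATES}")
    if years_since_event < 1:
        raise ValueError("years_since_event must be >= 1")

    def fixed(v: float) -> AnnualProbability:
        return AnnualProbability(value=v, source="fixed_rate")

    if state == "stroke_y1":
        return {
            "stroke_relapse": fixed(rates.stroke_relapse_year1),
            "chd": fixed(rates.chd_after_stroke),
            "cvd_death": fixed(rates.mort_stroke_year1),
        }
    if state == "post_stroke":
        return {
            "stroke_relapse": fixed(rates.stroke_relapse_later(years_since_event)),
            "chd": fixed(rates.chd_after_post_stroke),
            "cvd_death": fixed(rates.mort_post_stroke),
        }
    if state == "chd_y1":
        return {
            "chd_relapse": fixed(rates.chd_relapse_year1),
            "stroke": fixed(rates.stroke_after_chd),
            "cvd_death": fixed(rates.mort_chd_year1),
        }
    return {
        "chd_relapse": fixed(rates.chd_relapse_later),
        "stroke": fixed(rates.stroke_after_post_chd),
        "cvd_death": fixed(rates.mort_post_chd),
    }
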