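"""Model parameterization: domain types, defaults, config I/O, and perturbation.

The complete base-case parameterization of the cost-effectiveness model lives
here: baseline risk-factor distributions of the trial population, the Weibull
first-stroke incidence, the treatment effect (hazard ratio for first stroke),
fixed annual transition rates for recurrence and cardiovascular mortality, the
life table for non-CVD mortality, unit costs, health-state utilities,
adherence/disability/rehabilitation rates, and economic settings (discount
rate, willingness-to-pay thresholds).

Every numeric default mirrors the published parameter table; two inputs the
main text does not print — the base-case Weibull (scale, shape) and the
sex-specific 10-year coronary-heart-disease risk-equation coefficients — are
derived at load time from editable packaged files (a calibration-target CSV
and a coefficient CSV whose shipped values are synthetic placeholders; see
``docs/methods.md``).

Each parameter that enters the sensitivity analyses carries an
:class:`UncertainParameter` spec (distribution family, base value, range
and/or SD) used by the one-way and probabilistic sensitivity machinery.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, fields, is_dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import yaml


class ValidationError(ValueError):
    """A parameter value violates the documented schema."""


class RangeError(ValidationError):
    """A parameter value lies outside its admissible range."""


class ConfigurationError(ValueError):
    """A structural configuration problem (unknown field, unsupported family)."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise RangeError(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class WeibullIncidence:
    """Weibull hazard for first stroke: S(t) = exp(-scale * t**shape).

    ``scale`` is the per-year**shape hazard scale (lambda), ``shape`` the
    dimensionless shape (gamma). The annual transition probability between
    integer state-times t and t+1 is ``1 - S(t+1)/S(t)``.
    """

    scale: float
    shape: float

    def validate(self) -> None:
        _require(self.scale > 0, f"weibull.scale must be > 0, got {self.scale}")
        _require(self.shape > 0, f"weibull.shape must be > 0, got {self.shape}")


@dataclass
class TreatmentEffect:
    """Hazard ratio for first stroke, combination arm vs control.

    ``benefit_duration_years`` caps how long the hazard ratio applies
    (``inf`` = lifelong, the base case); scenario analyses set it to 5 or 10.
    """

    hazard_ratio: float = 0.79
    ci_low: float = 0.68
    ci_high: float = 0.93
    benefit_duration_years: float = math.inf

    def validate(self) -> None:
        _require(self.hazard_ratio > 0, "effect.hazard_ratio must be > 0")
        _require(
            0 < self.ci_low <= self.hazard_ratio <= self.ci_high,
            f"effect CI must satisfy 0 < low <= HR <= high, got "
            f"({self.ci_low}, {self.hazard_ratio}, {self.ci_high})",
        )
        _require(self.benefit_duration_years > 0, "effect.benefit_duration_years must be > 0")


@dataclass
class CHDRiskModel:
    """Sex-specific 10-year CHD risk equation.

    Ten-year risk is ``P = 1 - S10 ** exp(f(x, M))`` with linear predictor
    ``f(x, M) = sum_i beta_i * (x_i - M_i)`` over the risk factors, where
    ``M_i`` are the reference means and ``S10`` the baseline 10-year survival.
    """

    sex: str
    factors: list[str]
    coefficients: list[float]
    reference_means: list[float]
    baseline_survival_10y: float

    def validate(self) -> None:
        if not (len(self.factors) == len(self.coefficients) == len(self.reference_means)):
            raise ConfigurationError(
                f"chd model ({self.sex}): factors/coefficients/reference_means "
                "must have equal length"
            )
        _require(
            0 < self.baseline_survival_10y <= 1,
            f"chd model ({self.sex}): baseline_survival_10y must be in (0, 1]",
        )
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"chd model sex must be male/female, got {self.sex!r}")


@dataclass
class TransitionRates:
    """Fixed annual probabilities for recurrence, cross-events, and CVD death.

    The late stroke-relapse probability is a piecewise-linear schedule in
    years since the stroke, from ``stroke_relapse_y2`` in the second year down
    to ``stroke_relapse_late`` at ``stroke_relapse_late_year`` and beyond.
    """

    stroke_relapse_year1: float = 0.17
    stroke_relapse_y2: float = 0.09
    stroke_relapse_late: float = 0.02
    stroke_relapse_late_year: int = 10
    chd_after_stroke: float = 0.004
    chd_after_post_stroke: float = 0.004
    stroke_after_chd: float = 0.004
    stroke_after_post_chd: float = 0.004
    chd_relapse_year1: float = 0.025
    chd_relapse_later: float = 0.012
    mort_stroke_year1: float = 0.15
    mort_post_stroke: float = 0.03
    mort_chd_year1: float = 0.028
    mort_post_chd: float = 0.015

    _PROBS = (
        "stroke_relapse_year1",
        "stroke_relapse_y2",
        "stroke_relapse_late",
        "chd_after_stroke",
        "chd_after_post_stroke",
        "stroke_after_chd",
        "stroke_after_post_chd",
        "chd_relapse_year1",
        "chd_relapse_later",
        "mort_stroke_year1",
        "mort_post_stroke",
        "mort_chd_year1",
        "mort_post_chd",
    )

    def validate(self) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"rates.{name} must be in [0, 1], got {v}")
        _require(self.stroke_relapse_late_year >= 2, "rates.stroke_relapse_late_year must be >= 2")

    def stroke_relapse_later(self, years_since_stroke: float) -> float:
        """Relapse probability for post-stroke years (years_since_stroke >= 2)."""
        y0, y1 = 2, self.stroke_relapse_late_year
        if years_since_stroke <= y0:
            return self.stroke_relapse_y2
        if years_since_stroke >= y1:
            return self.stroke_relapse_late
        frac = (years_since_stroke - y0) / (y1 - y0)
        return self.stroke_relapse_y2 + frac * (self.stroke_relapse_late - self.stroke_relapse_y2)


@dataclass
class LifeTable:
    """Age- and sex-specific annual non-CVD mortality probabilities.

    Ages run contiguously from ``age_min`` to ``age_max`` inclusive. The
    packaged default is a synthetic Gompertz table anchored to the printed
    per-mille bounds (1.68 per mille at the youngest supported age, 507.28 per
    mille at the oldest), identical for both sexes; a user CSV with columns
    ``age, sex, qx`` overrides it.
    """

    age_min: int
    age_max: int
    qx_male: list[float]
    qx_female: list[float]

    def validate(self) -> None:
        n = self.age_max - self.age_min + 1
        if not (len(self.qx_male) == len(self.qx_female) == n):
            raise ValidationError("life_table: qx arrays must span age_min..age_max contiguously")
        for sex, qx in (("male", self.qx_male), ("female", self.qx_female)):
            for q in qx:
                _require(0.0 <= q <= 1.0, f"life_table ({sex}): qx {q} outside [0, 1]")

    def qx(self, age: float, sex: str, clamp: bool = False) -> float:
        idx = int(math.floor(age)) - self.age_min
        if idx < 0 or idx >= len(self.qx_male):
            if not clamp:
                raise LookupError(
                    f"age {age} outside life table range "
                    f"[{self.age_min}, {self.age_max}] (pass clamp=True to clip)"
                )
            idx = min(max(idx, 0), len(self.qx_male) - 1)
        return (self.qx_male if sex == "male" else self.qx_female)[idx]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.qx_male), np.asarray(self.qx_female)

    @classmethod
    def gompertz(
        cls,
        age_min: int = 35,
        age_max: int = 100,
        q_young: float = 0.00168,
        q_old: float = 0.50728,
    ) -> "LifeTable":
        """Synthetic Gompertz table q(a) = A * exp(B * a) through the anchors."""
        b = math.log(q_old / q_young) / (age_max - age_min)
        a = q_young / math.exp(b * age_min)
        qx = [min(1.0, a * math.exp(b * age)) for age in range(age_min, age_max + 1)]
        return cls(age_min=age_min, age_max=age_max, qx_male=list(qx), qx_female=list(qx))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        rows: dict[tuple[int, str], float] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows[(int(rec["age"]), rec["sex"])] = float(rec["qx"])
        ages = sorted({a for a, _ in rows})
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError(f"life table CSV {path}: ages must be contiguous")
        male = [rows[(a, "male")] for a in ages]
        female = [rows[(a, "female")] for a in ages]
        return cls(age_min=ages[0], age_max=ages[-1], qx_male=male, qx_female=female)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "sex", "qx"])
            for sex, qx in (("male", self.qx_male), ("female", self.qx_female)):
                for age, q in zip(range(self.age_min, self.age_max + 1), qx):
                    w.writerow([age, sex, repr(q)])


#: drug classes whose per-day prices appear in the parameter table
DRUG_CLASSES = (
    "enalapril",
    "enalapril_folic",
    "acei",
    "arb",
    "ccb",
    "diuretic",
    "beta_blocker",
    "lipid_lowering",
    "glucose_lowering",
    "antiplatelet",
)

#: concomitant classes (everything but the two study drugs)
CONCOMITANT_CLASSES = DRUG_CLASSES[2:]


@dataclass
class CostParameters:
    """Unit costs in USD; RMB renderings use ``exchange_rate`` (6.45 RMB/USD)."""

    drug_unit_prices: dict[str, float] = field(
        default_factory=lambda: {
            "enalapril": 0.09,
            "enalapril_folic": 0.74,
            "acei": 0.13,
            "arb": 0.08,
            "ccb": 0.25,
            "diuretic": 0.29,
            "beta_blocker": 0.03,
            "lipid_lowering": 0.08,
            "glucose_lowering": 0.04,
            "antiplatelet": 0.05,
        }
    )
    # usage share of each concomitant class; defaults calibrated so the annual
    # concomitant cost matches the in-trial average (~$16.7/yr), equal across arms
    concomitant_usage: dict[str, float] = field(
        default_factory=lambda: {c: 0.048 for c in CONCOMITANT_CLASSES}
    )
    event_costs_30d: dict[str, float] = field(
        default_factory=lambda: {
            "ischemic_stroke": 1529.18,
            "hemorrhagic_stroke": 3207.55,
            "chd": 4696.39,
        }
    )
    rehab_monthly: dict[str, float] = field(
        default_factory=lambda: {"training": 200.93, "checking": 7.91, "home_care": 465.12}
    )
    # month counts per post-stroke year (rest of first year vs later years)
    rehab_months_year1: dict[str, float] = field(
        default_factory=lambda: {"training": 3.0, "checking": 9.0}
    )
    rehab_months_later: dict[str, float] = field(
        default_factory=lambda: {"training": 0.0, "checking": 12.0}
    )
    home_care_months: float = 12.0
    chd_annual_med_cost: float = 58.40
    exchange_rate: float = 6.45

    def validate(self) -> None:
        for group_name, group in (
            ("drug_unit_prices", self.drug_unit_prices),
            ("event_costs_30d", self.event_costs_30d),
            ("rehab_monthly", self.rehab_monthly),
            ("rehab_months_year1", self.rehab_months_year1),
            ("rehab_months_later", self.rehab_months_later),
        ):
            for k, v in group.items():
                _require(v >= 0, f"costs.{group_name}.{k} must be >= 0, got {v}")
        for k, v in self.concomitant_usage.items():
            _require(0 <= v <= 1, f"costs.concomitant_usage.{k} must be in [0, 1], got {v}")
        _require(self.exchange_rate > 0, "costs.exchange_rate must be > 0")
        _require(self.home_care_months >= 0, "costs.home_care_months must be >= 0")
        _require(self.chd_annual_med_cost >= 0, "costs.chd_annual_med_cost must be >= 0")

    def to_rmb(self, usd: float) -> float:
        return usd * self.exchange_rate


@dataclass
class UtilityParameters:
    """Health-state utilities on the 0 (death) .. 1 (perfect health) scale."""

    pre_cvd: float = 0.90
    stroke_y1: float = 0.76
    stroke_later: float = 0.79
    stroke_recur_y1: float = 0.30
    stroke_recur_later: float = 0.33
    chd_y1: float = 0.77
    chd_later: float = 0.89
    chd_recur_y1: float = 0.64
    chd_recur_later: float = 0.76

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(0.0 <= v <= 1.0, f"utilities.{f.name} must be in [0, 1], got {v}")


@dataclass
class BehaviorParameters:
    """Adherence, post-stroke sequela rates, and the ischemic share of strokes.

    ``p_ischemic`` (share of modeled strokes that are ischemic rather than
    hemorrhagic) is not a published quantity; the default 0.80 is a
    documented assumption needed to choose between the two printed 30-day
    stroke hospitalization costs.
    """

    adherence_folic: float = 0.692
    adherence_enalapril: float = 0.691
    disability_rate: float = 0.39
    rehabilitation_rate: float = 0.58
    p_ischemic: float = 0.80

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(0.0 <= v <= 1.0, f"behavior.{f.name} must be in [0, 1], got {v}")


@dataclass
class EconomicSettings:
    discount_rate: float = 0.05
    gdp_per_capita: float = 12544.0
    wtp_per_qaly: float = 37663.0
    in_trial_years: float = 4.5
    lifetime_max_age: int = 100

    def validate(self) -> None:
        _require(0.0 <= self.discount_rate <= 0.08, "econ.discount_rate must be in [0, 0.08]")
        _require(self.gdp_per_capita > 0, "econ.gdp_per_capita must be > 0")
        _require(self.wtp_per_qaly > 0, "econ.wtp_per_qaly must be > 0")
        _require(self.lifetime_max_age > 0, "econ.lifetime_max_age must be > 0")


@dataclass
class PopulationDistributions:
    """Marginal baseline risk-factor distributions of the simulated cohort.

    Continuous factors are sampled from normals truncated at
    ``truncation_sd`` standard deviations; binary factors at the printed
    prevalences. MTHFR genotype, folate, and homocysteine marginals are not
    printed in the main text: the defaults below are documented placeholders
    used only for subgroup routing, never in base-case transition math.
    """

    age_mean: float = 60.0
    age_sd: float = 7.53
    prop_male: float = 0.41
    total_chol_mean: float = 213.6
    total_chol_sd: float = 46.0
    hdl_c_mean: float = 52.0
    hdl_c_sd: float = 14.0
    sbp_mean: float = 139.7
    sbp_sd: float = 11.1
    prop_smoker: float = 0.23
    prop_diabetes: float = 0.03
    mthfr_probs: dict[str, float] = field(
        default_factory=lambda: {"CC": 1 / 3, "CT": 1 / 3, "TT": 1 / 3}
    )
    folate_log_median: float = 8.0  # ng/mL, placeholder
    folate_log_sigma: float = 0.4
    homocysteine_log_median: float = 13.0  # umol/L, placeholder
    homocysteine_log_sigma: float = 0.35
    truncation_sd: float = 4.0

    def validate(self) -> None:
        for name in ("age_sd", "total_chol_sd", "hdl_c_sd", "sbp_sd"):
            _require(getattr(self, name) > 0, f"population.{name} must be > 0")
        for name in ("prop_male", "prop_smoker", "prop_diabetes"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"population.{name} must be in [0, 1], got {v}")
        total = sum(self.mthfr_probs.values())
        _require(abs(total - 1.0) < 1e-9, "population.mthfr_probs must sum to 1")
        _require(self.truncation_sd > 0, "population.truncation_sd must be > 0")


_FAMILIES = ("beta", "gamma", "lognormal", "normal", "fixed")


@dataclass
class UncertainParameter:
    """Uncertainty spec for one scalar parameter (dotted ``path`` into the set).

    ``family`` is the sampling distribution for the probabilistic sensitivity
    analysis; ``low``/``high`` are the one-way sensitivity bounds. When ``sd``
    is given (printed SDs for utilities) beta/normal sampling moment-matches
    (base, sd) directly; otherwise beta is moment-matched on the bounded
    support [low, high] with SD (high - low)/3.92, and gamma/lognormal use the
    same range-implied SD on their natural supports.
    """

    path: str
    family: str
    base: float
    low: float
    high: float
    sd: float | None = None

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"uncertainty[{self.path}]: unsupported family {self.family!r}"
            )
        _require(
            self.low <= self.base <= self.high,
            f"uncertainty[{self.path}]: bounds ({self.low}, {self.high}) "
            f"must bracket base {self.base}",
        )
        if self.sd is not None:
            _require(self.sd >= 0, f"uncertainty[{self.path}]: sd must be >= 0")


@dataclass
class SubgroupSpec:
    """A patient subgroup with its own first-stroke Weibull and hazard ratio.

    ``predicate`` is a boolean expression over patient fields (evaluated
    against the cohort table, e.g. ``"sex == 'male'"`` or
    ``"age >= 55 and age < 65"``). Overrides left ``None`` fall back to the
    base-case values.
    """

    name: str
    predicate: str
    weibull: WeibullIncidence | None = None
    hazard_ratio: float | None = None
    population: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("subgroup name must be non-empty")
        if self.weibull is not None:
            self.weibull.validate()
        if self.hazard_ratio is not None:
            _require(self.hazard_ratio > 0, f"subgroup {self.name}: hazard_ratio must be > 0")


# ---------------------------------------------------------------------------
# The parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    population: PopulationDistributions
    weibull: WeibullIncidence
    effect: TreatmentEffect
    chd_models: dict[str, CHDRiskModel]
    rates: TransitionRates
    life_table: LifeTable
    costs: CostParameters
    utilities: UtilityParameters
    behavior: BehaviorParameters
    econ: EconomicSettings
    uncertainty: dict[str, UncertainParameter]
    subgroups: list[SubgroupSpec] = field(default_factory=list)

    def validate(self) -> "ParameterSet":
        self.population.validate()
        self.weibull.validate()
        self.effect.validate()
        for m in self.chd_models.values():
            m.validate()
        for sex in ("male", "female"):
            if sex not in self.chd_models:
                raise ConfigurationError(f"chd_models missing sex {sex!r}")
        self.rates.validate()
        self.life_table.validate()
        self.costs.validate()
        self.utilities.validate()
        self.behavior.validate()
        self.econ.validate()
        for u in self.uncertainty.values():
            u.validate()
        for s in self.subgroups:
            s.validate()
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Packaged external inputs
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("folicsim.data").joinpath(name)))


def load_chd_models(path: str | Path | None = None) -> dict[str, CHDRiskModel]:
    """Read the CHD risk-equation file (sex, factor, beta, reference_mean).

    The packaged default file contains *synthetic placeholder* coefficients —
    the published equation's coefficients live in its source cohort study and
    are not reproduced here. Replace via this CSV for substantive use.
    """
    path = _data_path("chd_model_synthetic.csv") if path is None else Path(path)
    rows: dict[str, dict[str, tuple[float, float]]] = {"male": {}, "female": {}}
    s10: dict[str, float] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            sex = rec["sex"]
            if rec["factor"] == "baseline_survival_10y":
                s10[sex] = float(rec["beta"])
            else:
                rows[sex][rec["factor"]] = (float(rec["beta"]), float(rec["reference_mean"]))
    models = {}
    for sex in ("male", "female"):
        if sex not in s10:
            raise ConfigurationError(f"chd model file {path}: missing baseline_survival_10y ({sex})")
        factors = list(rows[sex])
        models[sex] = CHDRiskModel(
            sex=sex,
            factors=factors,
            coefficients=[rows[sex][f][0] for f in factors],
            reference_means=[rows[sex][f][1] for f in factors],
            baseline_survival_10y=s10[sex],
        )
    return models


def load_stroke_targets(path: str | Path | None = None) -> list[tuple[float, float, str]]:
    """Read first-stroke calibration targets (time_years, cumulative_incidence, arm)."""
    path = _data_path("stroke_targets_synthetic.csv") if path is None else Path(path)
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append((float(rec["time_years"]), float(rec["cumulative_incidence"]), rec["arm"]))
    return out


def default_weibull(
    targets: list[tuple[float, float, str]] | None = None, shape: float = 1.0
) -> WeibullIncidence:
    """Control-arm Weibull implied by the packaged calibration target.

    With a single target point (t*, P*) and the shape fixed, the scale is the
    closed form ``-ln(1 - P*) / t***shape``. The general least-squares fitter
    lives in :mod:`folicsim.calibration`; for multi-point target files use it
    directly.
    """
    targets = load_stroke_targets() if targets is None else targets
    control = [(t, p) for t, p, arm in targets if arm == "control"]
    if len(control) != 1:
        raise ConfigurationError(
            "default_weibull expects exactly one control-arm target point; "
            "use folicsim.calibration.fit_weibull for multi-point targets"
        )
    t_star, p_star = control[0]
    scale = -math.log(1.0 - p_star) / t_star**shape
    return WeibullIncidence(scale=scale, shape=shape)


# ---------------------------------------------------------------------------
# Default uncertainty specification
# ---------------------------------------------------------------------------


def _pm20(base: float, cap: float | None = None) -> tuple[float, float]:
    lo, hi = 0.8 * base, 1.2 * base
    if cap is not None:
        hi = min(hi, cap)
    return lo, hi


def default_uncertainty() -> dict[str, UncertainParameter]:
    """The printed uncertainty table: family + base + range (or SD) per parameter."""
    specs: list[UncertainParameter] = []

    def add(path, family, base, low, high, sd=None):
        specs.append(UncertainParameter(path, family, base, low, high, sd))

    add("effect.hazard_ratio", "lognormal", 0.79, 0.68, 0.93)

    add("behavior.adherence_folic", "beta", 0.692, *_pm20(0.692, cap=1.0))
    add("behavior.adherence_enalapril", "beta", 0.691, *_pm20(0.691, cap=1.0))
    add("behavior.disability_rate", "beta", 0.39, 0.20, 0.80)
    add("behavior.rehabilitation_rate", "beta", 0.58, 0.0, 0.70)

    for name, base in (
        ("stroke_relapse_year1", 0.17),
        ("stroke_relapse_y2", 0.09),
        ("stroke_relapse_late", 0.02),
        ("chd_after_stroke", 0.004),
        ("chd_after_post_stroke", 0.004),
        ("stroke_after_chd", 0.004),
        ("stroke_after_post_chd", 0.004),
        ("chd_relapse_year1", 0.025),
        ("chd_relapse_later", 0.012),
        ("mort_stroke_year1", 0.15),
        ("mort_post_stroke", 0.03),
        ("mort_chd_year1", 0.028),
        ("mort_post_chd", 0.015),
    ):
        add(f"rates.{name}", "beta", base, *_pm20(base))

    drug_ranges = {
        "enalapril": (0.03, 0.22),
        "enalapril_folic": _pm20(0.74),
        "acei": (0.11, 0.38),
        "arb": (0.07, 0.54),
        "ccb": (0.14, 0.47),
        "diuretic": (0.27, 0.30),
        "beta_blocker": (0.02, 0.05),
        "lipid_lowering": (0.03, 0.65),
        "glucose_lowering": (0.03, 0.24),
        "antiplatelet": (0.05, 0.08),
    }
    bases = CostParameters().drug_unit_prices
    for drug, (lo, hi) in drug_ranges.items():
        add(f"costs.drug_unit_prices.{drug}", "gamma", bases[drug], lo, hi)

    for ev, base in (("ischemic_stroke", 1529.18), ("hemorrhagic_stroke", 3207.55), ("chd", 4696.39)):
        add(f"costs.event_costs_30d.{ev}", "gamma", base, *_pm20(base))
    for item, base in (("training", 200.93), ("checking", 7.91), ("home_care", 465.12)):
        add(f"costs.rehab_monthly.{item}", "gamma", base, *_pm20(base))

    add("utilities.pre_cvd", "beta", 0.90, *_pm20(0.90, cap=1.0), sd=0.12)
    add("utilities.stroke_y1", "beta", 0.76, *_pm20(0.76, cap=1.0))
    add("utilities.stroke_later", "beta", 0.79, *_pm20(0.79, cap=1.0))
    add("utilities.stroke_recur_y1", "beta", 0.30, *_pm20(0.30))
    add("utilities.stroke_recur_later", "beta", 0.33, *_pm20(0.33))
    add("utilities.chd_y1", "beta", 0.77, 0.75, 0.78)
    add("utilities.chd_later", "beta", 0.89, *_pm20(0.89, cap=1.0), sd=0.17)
    add("utilities.chd_recur_y1", "beta", 0.64, *_pm20(0.64))
    add("utilities.chd_recur_later", "beta", 0.76, *_pm20(0.76, cap=1.0))

    # varied in one-way SA only; held fixed in the PSA
    add("econ.discount_rate", "fixed", 0.05, 0.0, 0.08)

    return {s.path: s for s in specs}


def default_parameters() -> ParameterSet:
    """The packaged base case (every printed default, externals from data files)."""
    return ParameterSet(
        population=PopulationDistributions(),
        weibull=default_weibull(),
        effect=TreatmentEffect(),
        chd_models=load_chd_models(),
        rates=TransitionRates(),
        life_table=LifeTable.gompertz(),
        costs=CostParameters(),
        utilities=UtilityParameters(),
        behavior=BehaviorParameters(),
        econ=EconomicSettings(),
        uncertainty=default_uncertainty(),
        subgroups=[],
    ).validate()


# ---------------------------------------------------------------------------
# Dotted-path access and perturbation
# ---------------------------------------------------------------------------


def get_param(params: ParameterSet, path: str) -> Any:
    obj: Any = params
    for part in path.split("."):
        if is_dataclass(obj) and not isinstance(obj, type):
            if not hasattr(obj, part):
                raise ConfigurationError(f"unknown parameter path {path!r} (at {part!r})")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown parameter path {path!r} (at {part!r})")
            obj = obj[part]
        else:
            raise ConfigurationError(f"path {path!r} descends into a scalar at {part!r}")
    return obj


def set_param(params: ParameterSet, path: str, value: Any) -> None:
    parts = path.split(".")
    obj: Any = params
    for part in parts[:-1]:
        if is_dataclass(obj) and not isinstance(obj, type):
            if not hasattr(obj, part):
                raise ConfigurationError(f"unknown parameter path {path!r} (at {part!r})")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown parameter path {path!r} (at {part!r})")
            obj = obj[part]
        else:
            raise ConfigurationError(f"path {path!r} descends into a scalar at {part!r}")
    leaf = parts[-1]
    if is_dataclass(obj) and not isinstance(obj, type):
        if not hasattr(obj, leaf):
            raise ConfigurationError(f"unknown parameter path {path!r} (at {leaf!r})")
        setattr(obj, leaf, value)
    elif isinstance(obj, dict):
        if leaf not in obj:
            raise ConfigurationError(f"unknown parameter path {path!r} (at {leaf!r})")
        obj[leaf] = value
    else:
        raise ConfigurationError(f"path {path!r} descends into a scalar at {leaf!r}")


def perturb(params: ParameterSet, draws: dict[str, float]) -> ParameterSet:
    """Return a new ParameterSet with the listed parameters replaced.

    The input object is never modified; the result is re-validated, so a draw
    that violates a type invariant raises :class:`RangeError`.
    """
    out = params.copy()
    for path, value in draws.items():
        set_param(out, path, value)
    # a sampled hazard ratio may fall outside the printed CI; the CI is
    # dispersion metadata, so widen it to keep the bracket invariant honest
    if "effect.hazard_ratio" in draws:
        out.effect.ci_low = min(out.effect.ci_low, out.effect.hazard_ratio)
        out.effect.ci_high = max(out.effect.ci_high, out.effect.hazard_ratio)
    return out.validate()


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------


def _beta_from_mean_sd(mean: float, sd: float, path: str) -> tuple[float, float]:
    var = sd * sd
    if not 0 < mean < 1 or var >= mean * (1 - mean):
        raise ConfigurationError(
            f"uncertainty[{path}]: beta moment match infeasible (mean={mean}, sd={sd})"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def sample_psa_draw(
    params: ParameterSet,
    spec: dict[str, UncertainParameter] | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """One joint parameter draw for the probabilistic sensitivity analysis.

    Parameters with ``family='fixed'`` (e.g. the discount rate) are excluded.
    Beta draws with a printed SD are moment-matched on (0, 1); beta draws
    specified by a range are moment-matched on the range itself with SD
    (high - low)/3.92. Gamma draws moment-match (base, range-implied SD) on
    (0, inf). The hazard ratio samples log-normally with sigma implied by its
    95% CI. Deterministic given the seed; parameters are drawn in sorted path
    order.
    """
    spec = params.uncertainty if spec is None else spec
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    draw: dict[str, float] = {}
    for path in sorted(spec):
        u = spec[path]
        u.validate()
        if u.family == "fixed":
            continue
        if u.family == "beta":
            if u.sd is not None:
                a, b = _beta_from_mean_sd(u.base, u.sd, path)
                draw[path] = float(rng.beta(a, b))
            elif u.high > u.low:
                width = u.high - u.low
                a, b = _beta_from_mean_sd((u.base - u.low) / width, 1.0 / 3.92, path)
                draw[path] = float(u.low + width * rng.beta(a, b))
            else:
                draw[path] = u.base
        elif u.family == "gamma":
            sd = u.sd if u.sd is not None else (u.high - u.low) / 3.92
            if sd == 0 or u.base == 0:
                draw[path] = u.base
            else:
                shape = (u.base / sd) ** 2
                draw[path] = float(rng.gamma(shape, sd * sd / u.base))
        elif u.family == "lognormal":
            sigma = (math.log(u.high) - math.log(u.low)) / 3.92
            draw[path] = float(rng.lognormal(math.log(u.base), sigma))
        elif u.family == "normal":
            sd = u.sd if u.sd is not None else (u.high - u.low) / 3.92
            draw[path] = float(rng.normal(u.base, sd))
        else:  # pragma: no cover - guarded by validate()
            raise ConfigurationError(f"unsupported family {u.family!r}")
    return draw


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------


def _inf_to_none(v: float) -> float | None:
    return None if math.isinf(v) else v


def to_dict(params: ParameterSet) -> dict[str, Any]:
    """Plain-dict rendering of a ParameterSet (YAML-serializable)."""
    p = params
    return {
        "population": {f.name: getattr(p.population, f.name) for f in fields(p.population)},
        "weibull": {"scale": p.weibull.scale, "shape": p.weibull.shape},
        "effect": {
            "hazard_ratio": p.effect.hazard_ratio,
            "ci_low": p.effect.ci_low,
            "ci_high": p.effect.ci_high,
            "benefit_duration_years": _inf_to_none(p.effect.benefit_duration_years),
        },
        "chd_models": {
            sex: {
                "factors": list(m.factors),
                "coefficients": list(m.coefficients),
                "reference_means": list(m.reference_means),
                "baseline_survival_10y": m.baseline_survival_10y,
            }
            for sex, m in p.chd_models.items()
        },
        "rates": {
            f.name: getattr(p.rates, f.name)
            for f in fields(p.rates)
        },
        "life_table": {
            "age_min": p.life_table.age_min,
            "age_max": p.life_table.age_max,
            "qx_male": list(p.life_table.qx_male),
            "qx_female": list(p.life_table.qx_female),
        },
        "costs": {f.name: copy.deepcopy(getattr(p.costs, f.name)) for f in fields(p.costs)},
        "utilities": {f.name: getattr(p.utilities, f.name) for f in fields(p.utilities)},
        "behavior": {f.name: getattr(p.behavior, f.name) for f in fields(p.behavior)},
        "econ": {f.name: getattr(p.econ, f.name) for f in fields(p.econ)},
        "uncertainty": {
            path: {
                "family": u.family,
                "base": u.base,
                "low": u.low,
                "high": u.high,
                "sd": u.sd,
            }
            for path, u in p.uncertainty.items()
        },
        "subgroups": [
            {
                "name": s.name,
                "predicate": s.predicate,
                "weibull": None
                if s.weibull is None
                else {"scale": s.weibull.scale, "shape": s.weibull.shape},
                "hazard_ratio": s.hazard_ratio,
                "population": dict(s.population),
            }
            for s in p.subgroups
        ],
    }


def _deep_merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in out and prefix not in ("uncertainty.", "costs.drug_unit_prices."):
            raise ConfigurationError(f"unknown configuration field {path!r}")
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val, prefix=f"{path}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


def from_dict(d: dict[str, Any]) -> ParameterSet:
    eff = d["effect"]
    benefit = eff.get("benefit_duration_years")
    params = ParameterSet(
        population=PopulationDistributions(**d["population"]),
        weibull=WeibullIncidence(**d["weibull"]),
        effect=TreatmentEffect(
            hazard_ratio=eff["hazard_ratio"],
            ci_low=eff["ci_low"],
            ci_high=eff["ci_high"],
            benefit_duration_years=math.inf if benefit is None else float(benefit),
        ),
        chd_models={
            sex: CHDRiskModel(sex=sex, **m) for sex, m in d["chd_models"].items()
        },
        rates=TransitionRates(**d["rates"]),
        life_table=LifeTable(**d["life_table"]),
        costs=CostParameters(**d["costs"]),
        utilities=UtilityParameters(**d["utilities"]),
        behavior=BehaviorParameters(**d["behavior"]),
        econ=EconomicSettings(**d["econ"]),
        uncertainty={
            path: UncertainParameter(path=path, **u) for path, u in d["uncertainty"].items()
        },
        subgroups=[
            SubgroupSpec(
                name=s["name"],
                predicate=s["predicate"],
                weibull=None if s.get("weibull") is None else WeibullIncidence(**s["weibull"]),
                hazard_ratio=s.get("hazard_ratio"),
                population=dict(s.get("population", {})),
            )
            for s in d.get("subgroups", [])
        ],
    )
    return params.validate()


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load a parameter configuration, filling omitted fields with the defaults.

    The YAML file holds any subset of the full schema (see ``to_dict``); an
    empty or absent file yields the packaged base case. Two convenience keys,
    ``life_table_csv`` and ``chd_model_csv``, point at override CSVs. Unknown
    fields raise :class:`ConfigurationError`; out-of-range values raise
    :class:`RangeError` naming the offending field.
    """
    base = to_dict(default_parameters())
    override: dict[str, Any] = {}
    life_csv = chd_csv = None
    if config_path is not None:
        with open(config_path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ConfigurationError(f"config {config_path}: top level must be a mapping")
        life_csv = override.pop("life_table_csv", None)
        chd_csv = override.pop("chd_model_csv", None)
    merged = _deep_merge(base, override)
    params = from_dict(merged)
    if life_csv is not None:
        params.life_table = LifeTable.from_csv(life_csv)
    if chd_csv is not None:
        params.chd_models = load_chd_models(chd_csv)
    return params.validate()


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet to YAML such that load_parameters round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False, default_flow_style=None)
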