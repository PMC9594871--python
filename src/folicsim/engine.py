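"""Discrete annual-cycle individual-level simulation over the six-state model.

States: pre-CVD -> {stroke, CHD} event-year tunnels -> {post-stroke, post-CHD}
-> death (absorbing). Tunnel states last exactly one cycle unless death or a
relapse (which re-enters the tunnel) intervenes. Each cycle one uniform draw
per patient resolves the competing events: the per-event annual probabilities
are combined as independent hazards (``h_i = -ln(1 - p_i)``), the total event
probability ``1 - exp(-sum h_i)`` is allocated proportionally to the hazards,
and the uniform is compared against the resulting partition of [0, 1). This is
order-free and reproducible. Stroke events are labelled ischemic/hemorrhagic
by rescaling the uniform within the stroke segment — no extra draw needed.

Randomness is counter-based: a Philox generator keyed by the run seed fills a
(patient x cycle) uniform matrix, so element (i, t) is a fixed counter
position independent of evaluation order, and paired arms share the matrix
(common random numbers). With a hazard ratio of 1 the two arms are
bit-identical.

Two equivalent execution paths exist: a scalar reference path
(:func:`step` / :func:`simulate_individual`) that records full trajectories,
and a vectorized cohort path (:func:`run_cohort`) used for production runs;
the test suite asserts their agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from types import SimpleNamespace
from typing import NamedTuple

import numpy as np

from . import economics, risk_models
from .parameters import ParameterSet
from .synthetic_population import Cohort, Patient

__all__ = [
    "HealthState",
    "SimulationSettings",
    "CycleRecord",
    "Trajectory",
    "StepResult",
    "step",
    "simulate_individual",
    "run_arm",
    "run_cohort",
    "uniform_matrix",
]

ARMS = ("folic", "control")


class HealthState(str, Enum):
    PRE_CVD = "pre_cvd"
    STROKE_Y1 = "stroke_y1"
    CHD_Y1 = "chd_y1"
    POST_STROKE = "post_stroke"
    POST_CHD = "post_chd"
    DEAD = "dead"


# integer codes for the vectorized path
_CODE = {
    HealthState.PRE_CVD: 0,
    HealthState.STROKE_Y1: 1,
    HealthState.CHD_Y1: 2,
    HealthState.POST_STROKE: 3,
    HealthState.POST_CHD: 4,
    HealthState.DEAD: 5,
}

#: allowed transition graph (scanned by the invariant tests)
ALLOWED_TRANSITIONS = {
    HealthState.PRE_CVD: {
        HealthState.PRE_CVD,
        HealthState.STROKE_Y1,
        HealthState.CHD_Y1,
        HealthState.DEAD,
    },
    HealthState.STROKE_Y1: {
        HealthState.POST_STROKE,
        HealthState.STROKE_Y1,
        HealthState.CHD_Y1,
        HealthState.DEAD,
    },
    HealthState.CHD_Y1: {
        HealthState.POST_CHD,
        HealthState.CHD_Y1,
        HealthState.STROKE_Y1,
        HealthState.DEAD,
    },
    HealthState.POST_STROKE: {
        HealthState.POST_STROKE,
        HealthState.STROKE_Y1,
        HealthState.CHD_Y1,
        HealthState.DEAD,
    },
    HealthState.POST_CHD: {
        HealthState.POST_CHD,
        HealthState.CHD_Y1,
        HealthState.STROKE_Y1,
        HealthState.DEAD,
    },
    HealthState.DEAD: set(),
}


@dataclass
class SimulationSettings:
    """Cohort-level run settings (cycle length is fixed at 1 year)."""

    n_patients: int = 10_000
    seed: int = 0
    max_age: int | None = None  # None -> params.econ.lifetime_max_age
    paired_arms: bool = True
    half_cycle: bool = False
    max_years: int | None = None  # optional horizon cap (e.g. in-trial runs)

    def resolve_max_age(self, params: ParameterSet) -> int:
        return params.econ.lifetime_max_age if self.max_age is None else self.max_age


@dataclass
class CycleRecord:
    cycle: int
    age: float
    state: HealthState
    years_since_event: int
    recurrent_stroke: bool
    recurrent_chd: bool
    event: str | None = None  # event drawn DURING this cycle (fires next cycle)
    subtype: str | None = None  # ischemic/hemorrhagic for the occupied stroke year
    cycle_weight: float = 1.0  # 0.5 in the death cycle under half-cycle correction


@dataclass
class Trajectory:
    patient_id: int
    records: list[CycleRecord] = field(default_factory=list)
    terminal_cause: str | None = None  # non_cvd | cvd | censored_at_horizon


class StepResult(NamedTuple):
    next_state: HealthState
    event: str | None  # none | noncvd_death | cvd_death | stroke | chd
    subtype: str | None  # subtype of a stroke event fired this step
    recurrent: bool  # whether the fired event is a recurrence


# ---------------------------------------------------------------------------
# Competing-event partition
# ---------------------------------------------------------------------------

_P_CAP = 1.0 - 1e-12


def _partition(probs: list[float], u: float) -> tuple[int, float]:
    """Resolve one uniform against competing annual probabilities.

    Returns ``(index, u_cond)`` where ``index`` is the fired event's position
    (``len(probs)`` = no event) and ``u_cond`` the uniform rescaled within the
    winning segment (used for sub-splitting, e.g. stroke subtype). A
    probability of exactly 1 forces that event (first such wins).
    """
    for i, p in enumerate(probs):
        if p >= 1.0:
            return i, u
    h = [-math.log1p(-p) for p in probs]
    total = sum(h)
    if total == 0.0:
        return len(probs), u
    p_any = -math.expm1(-total)
    edges = []
    acc = 0.0
    for hi in h:
        acc += hi
        edges.append(p_any * acc / total)
    lo = 0.0
    for i, edge in enumerate(edges):
        if u < edge:
            return i, (u - lo) / (edge - lo)
        lo = edge
    return len(probs), (u - p_any) / (1.0 - p_any) if p_any < 1.0 else u


# event orderings per state (death first, then CVD events) — fixed and documented
_EVENTS_PRE = ("noncvd_death", "stroke", "chd")
_EVENTS_STROKE = ("noncvd_death", "cvd_death", "stroke", "chd")
_EVENTS_CHD = ("noncvd_death", "cvd_death", "chd", "stroke")


def _state_probs(
    state: HealthState,
    state_year: int,
    params: ParameterSet,
    arm: str,
    age: float,
    patient,
) -> tuple[tuple[str, ...], list[float]]:
    q_nc = params.life_table.qx(age, patient.sex, clamp=True)
    if state is HealthState.PRE_CVD:
        p_stroke = risk_models.stroke_annual_prob(params.weibull, state_year)
        if arm == "folic":
            p_stroke = risk_models.apply_hazard_ratio(p_stroke, params.effect, state_year)
        view = SimpleNamespace(
            age=age,
            sbp=patient.sbp,
            total_chol=patient.total_chol,
            hdl_c=patient.hdl_c,
            diabetes=float(patient.diabetes),
            smoker=float(patient.smoker),
        )
        p10 = risk_models.chd_ten_year_risk(view, params.chd_models[patient.sex])
        p_chd = risk_models.annualize_ten_year(min(p10, _P_CAP)).value
        return _EVENTS_PRE, [q_nc, min(p_stroke.value, _P_CAP), p_chd]
    probs = risk_models.post_event_probs(state.value, max(state_year, 1), params.rates)
    if state in (HealthState.STROKE_Y1, HealthState.POST_STROKE):
        return _EVENTS_STROKE, [
            q_nc,
            probs["cvd_death"].value,
            probs["stroke_relapse"].value,
            probs["chd"].value,
        ]
    return _EVENTS_CHD, [
        q_nc,
        probs["cvd_death"].value,
        probs["chd_relapse"].value,
        probs["stroke"].value,
    ]


def step(
    patient,
    state: HealthState,
    state_year: int,
    params: ParameterSet,
    arm: str,
    uniform_draw: float,
    *,
    age: float | None = None,
    had_stroke: bool = False,
    had_chd: bool = False,
) -> StepResult:
    """One annual cycle for one patient: resolve the competing events.

    ``state_year`` is years in the current state: for pre-CVD it is also the
    Weibull state-time and the benefit-duration clock; for post states it is
    years since the event (tunnel year = 1). ``age`` defaults to
    ``patient.age + state_year`` (exact for pre-CVD); callers tracking full
    histories should pass the true current age. The same inputs and draw
    always give the same output.
    """
    state = HealthState(state)
    if state is HealthState.DEAD:
        raise ValueError("step called on an absorbed (dead) patient")
    if state_year < 0:
        raise ValueError("state_year must be >= 0")
    if not 0.0 <= uniform_draw < 1.0:
        raise ValueError("uniform_draw must be in [0, 1)")
    age = patient.age + state_year if age is None else age
    events, probs = _state_probs(state, state_year, params, arm, age, patient)
    idx, u_cond = _partition(probs, uniform_draw)

    if idx == len(probs):  # no event: tunnel exit or stay
        if state is HealthState.STROKE_Y1:
            return StepResult(HealthState.POST_STROKE, None, None, False)
        if state is HealthState.CHD_Y1:
            return StepResult(HealthState.POST_CHD, None, None, False)
        return StepResult(state, None, None, False)

    name = events[idx]
    if name == "noncvd_death":
        return StepResult(HealthState.DEAD, "noncvd_death", None, False)
    if name == "cvd_death":
        return StepResult(HealthState.DEAD, "cvd_death", None, False)
    if name == "stroke":
        subtype = "ischemic" if u_cond < params.behavior.p_ischemic else "hemorrhagic"
        return StepResult(HealthState.STROKE_Y1, "stroke", subtype, had_stroke)
    # chd
    return StepResult(HealthState.CHD_Y1, "chd", None, had_chd)


def simulate_individual(
    patient: Patient,
    arm: str,
    params: ParameterSet,
    settings: SimulationSettings,
    uniforms: np.ndarray | None = None,
) -> Trajectory:
    """Simulate one patient to death or the age horizon, recording each cycle.

    ``uniforms`` is the patient's row of the run's uniform matrix; paired-arm
    simulation passes the same row to both arms so that with a hazard ratio
    of 1 the trajectories coincide cycle-for-cycle.
    """
    max_age = settings.resolve_max_age(params)
    horizon = math.ceil(max_age - patient.age)
    if settings.max_years is not None:
        horizon = min(horizon, settings.max_years)
    if uniforms is None:
        uniforms = uniform_matrix(1, max(horizon, 1), settings.seed)[patient.id % 1]
    traj = Trajectory(patient_id=patient.id)
    state = HealthState.PRE_CVD
    state_year = 0
    had_stroke = had_chd = False
    recur_stroke = recur_chd = False
    subtype: str | None = None
    for t in range(horizon):
        age = patient.age + t
        if age >= max_age:
            break
        rec = CycleRecord(
            cycle=t,
            age=age,
            state=state,
            years_since_event=state_year if state is not HealthState.PRE_CVD else 0,
            recurrent_stroke=recur_stroke,
            recurrent_chd=recur_chd,
            subtype=subtype if state is HealthState.STROKE_Y1 else None,
        )
        result = step(
            patient,
            state,
            state_year,
            params,
            arm,
            float(uniforms[t]),
            age=age,
            had_stroke=had_stroke,
            had_chd=had_chd,
        )
        rec.event = result.event
        if settings.half_cycle and result.next_state is HealthState.DEAD:
            rec.cycle_weight = 0.5
        traj.records.append(rec)
        if result.next_state is HealthState.DEAD:
            traj.terminal_cause = "non_cvd" if result.event == "noncvd_death" else "cvd"
            return traj
        if result.event == "stroke":
            recur_stroke = had_stroke
            had_stroke = True
            subtype = result.subtype
            state, state_year = HealthState.STROKE_Y1, 1
        elif result.event == "chd":
            recur_chd = had_chd
            had_chd = True
            state, state_year = HealthState.CHD_Y1, 1
        elif state is HealthState.STROKE_Y1:
            state, state_year = HealthState.POST_STROKE, 2
        elif state is HealthState.CHD_Y1:
            state, state_year = HealthState.POST_CHD, 2
        else:
            state_year += 1
    traj.terminal_cause = "censored_at_horizon"
    return traj


# ---------------------------------------------------------------------------
# Vectorized cohort path
# ---------------------------------------------------------------------------


def uniform_matrix(n: int, t_max: int, seed: int) -> np.ndarray:
    """(n x t_max) uniforms from a Philox counter stream keyed by ``seed``."""
    gen = np.random.Generator(np.random.Philox(key=np.uint64(seed)))
    return gen.random((n, t_max))


def _cohort_arrays(cohort: Cohort, params: ParameterSet) -> dict[str, np.ndarray]:
    tab = cohort.table
    n = len(tab)
    is_male = (tab["sex"].to_numpy() == "male")
    lp_fixed = np.zeros(n)
    beta_age = np.zeros(n)
    m_age = np.zeros(n)
    log_s10 = np.zeros(n)
    values = {
        "sbp": tab["sbp"].to_numpy(float),
        "total_chol": tab["total_chol"].to_numpy(float),
        "hdl_c": tab["hdl_c"].to_numpy(float),
        "diabetes": tab["diabetes"].to_numpy(float),
        "smoker": tab["smoker"].to_numpy(float),
    }
    for sex, mask in (("male", is_male), ("female", ~is_male)):
        model = params.chd_models[sex]
        model.validate()
        log_s10[mask] = math.log(model.baseline_survival_10y)
        for factor, beta, mean in zip(model.factors, model.coefficients, model.reference_means):
            if factor == "age":
                beta_age[mask] = beta
                m_age[mask] = mean
            else:
                lp_fixed[mask] += beta * (values[factor][mask] - mean)
    return {
        "age0": tab["age"].to_numpy(float),
        "is_male": is_male,
        "lp_fixed": lp_fixed,
        "beta_age": beta_age,
        "m_age": m_age,
        "log_s10": log_s10,
    }


def _hazard_partition(probs: list[np.ndarray], u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized competing-event resolution; mirrors :func:`_partition`.

    Returns ``(choice, u_cond)``: ``choice[i]`` in 0..k-1 for the fired event,
    k for no event; ``u_cond`` the uniform rescaled within the chosen segment.
    """
    k = len(probs)
    h = [-np.log1p(-np.minimum(p, _P_CAP)) for p in probs]
    total = sum(h)
    p_any = -np.expm1(-total)
    safe_total = np.where(total > 0, total, 1.0)
    edges = []
    acc = np.zeros_like(total)
    for hi in h:
        acc = acc + hi
        edges.append(p_any * acc / safe_total)
    choice = np.full(u.shape, k, dtype=np.int8)
    u_cond = np.array(u, copy=True)
    lo = np.zeros_like(u)
    for i in range(k):
        hit = (choice == k) & (u < edges[i])
        width = edges[i] - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            u_cond = np.where(hit & (width > 0), (u - lo) / np.where(width > 0, width, 1.0), u_cond)
        choice = np.where(hit, i, choice)
        lo = edges[i]
    return choice, u_cond


def run_arm(
    cohort: Cohort,
    params: ParameterSet,
    settings: SimulationSettings,
    arm: str,
    uniforms: np.ndarray | None = None,
) -> economics.ArmResult:
    """Vectorized simulation of one treatment arm over the cohort."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if len(cohort) < 1:
        raise ValueError("cohort must be nonempty")
    n = len(cohort)
    max_age = settings.resolve_max_age(params)
    arrays = _cohort_arrays(cohort, params)
    age0 = arrays["age0"]
    t_max = max(int(math.ceil(max_age - age0.min())), 1)
    if settings.max_years is not None:
        t_max = min(t_max, settings.max_years)
    if uniforms is None:
        uniforms = uniform_matrix(n, t_max, settings.seed)
    elif uniforms.shape[0] != n or uniforms.shape[1] < t_max:
        raise ValueError(
            f"uniform matrix shape {uniforms.shape} incompatible with (n={n}, t_max={t_max})"
        )

    r = params.econ.discount_rate
    hr_years = params.effect.benefit_duration_years
    p_isch = params.behavior.p_ischemic
    qx_male, qx_female = params.life_table.as_arrays()
    age_min, age_max_tab = params.life_table.age_min, params.life_table.age_max

    # cycle-constant payoffs
    drug = economics.study_drug_annual_cost(arm, params)
    conc = economics.concomitant_annual_cost(params)
    psc = {
        y: economics.post_stroke_annual_cost(y, params.behavior, params.costs)
        for y in range(1, t_max + 3)
    }
    cmed = economics.post_chd_annual_cost(params.costs)
    cost_isch = params.costs.event_costs_30d["ischemic_stroke"]
    cost_hem = params.costs.event_costs_30d["hemorrhagic_stroke"]
    cost_chd = params.costs.event_costs_30d["chd"]
    u_of = {
        (s, rec): economics.utility_for(s, 2, rec, params.utilities)
        for s in ("pre_cvd", "stroke_y1", "chd_y1", "post_stroke", "post_chd")
        for rec in (False, True)
    }
    rates = params.rates
    rel_sched = np.array(
        [rates.stroke_relapse_later(y) for y in range(0, t_max + 3)]
    )  # index = years since stroke (entries <2 unused)

    # pre-CVD stroke probability depends only on the cycle index
    p_stroke_by_t = np.empty(t_max)
    for t in range(t_max):
        p = risk_models.stroke_annual_prob(params.weibull, t)
        if arm == "folic" and t < hr_years:
            p = risk_models.apply_hazard_ratio(p, params.effect, t)
        p_stroke_by_t[t] = min(p.value, _P_CAP)

    # state arrays
    state = np.zeros(n, dtype=np.int8)  # codes per _CODE
    ys = np.zeros(n, dtype=np.int32)  # years since event (post states)
    recur_stroke = np.zeros(n, dtype=bool)
    recur_chd = np.zeros(n, dtype=bool)
    had_stroke = np.zeros(n, dtype=bool)
    had_chd = np.zeros(n, dtype=bool)
    subtype = np.zeros(n, dtype=np.int8)  # 0 none, 1 ischemic, 2 hemorrhagic
    dead = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)
    first_stroke_year = np.full(n, -1, dtype=np.int32)
    # cycle at which the patient left the pre-CVD risk set (event, death, or
    # censoring); feeds the product-limit incidence estimate in calibration
    pre_exit_year = np.full(n, -1, dtype=np.int32)

    cost_cat = {c: np.zeros(n) for c in economics.COST_CATEGORIES}
    cost_cat_u = {c: np.zeros(n) for c in economics.COST_CATEGORIES}
    ly = np.zeros(n)
    qaly = np.zeros(n)
    ly_u = np.zeros(n)
    qaly_u = np.zeros(n)
    counts = {
        "first_stroke": 0,
        "stroke_total": 0,
        "first_chd": 0,
        "chd_total": 0,
        "cvd_death": 0,
        "noncvd_death": 0,
    }

    for t in range(t_max):
        age = age0 + t
        newly_censored = ~dead & ~censored & (age >= max_age)
        pre_exit_year[newly_censored & (state == 0)] = t
        censored |= newly_censored
        active = ~dead & ~censored
        if not active.any():
            break
        d = 1.0 / (1.0 + r) ** t

        # ---- payoffs for the state occupied this cycle ----
        cyc_cost = {c: np.zeros(n) for c in economics.COST_CATEGORIES}
        util = np.zeros(n)
        weight = np.ones(n)

        m_pre = active & (state == 0)
        m_s1 = active & (state == 1)
        m_c1 = active & (state == 2)
        m_ps = active & (state == 3)
        m_pc = active & (state == 4)

        cyc_cost["drug"][m_pre] = drug
        cyc_cost["concomitant"][m_pre] = conc
        util[m_pre] = u_of[("pre_cvd", False)]

        cyc_cost["ischemic_stroke"][m_s1 & (subtype == 1)] = cost_isch
        cyc_cost["hemorrhagic_stroke"][m_s1 & (subtype == 2)] = cost_hem
        cyc_cost["post"][m_s1] = psc[1]
        util[m_s1] = np.where(recur_stroke[m_s1], u_of[("stroke_y1", True)], u_of[("stroke_y1", False)])

        cyc_cost["chd"][m_c1] = cost_chd
        cyc_cost["post"][m_c1] += cmed
        util[m_c1] = np.where(recur_chd[m_c1], u_of[("chd_y1", True)], u_of[("chd_y1", False)])

        if m_ps.any():
            cyc_cost["post"][m_ps] = np.array([psc[int(y)] for y in ys[m_ps]])
            util[m_ps] = np.where(
                recur_stroke[m_ps], u_of[("post_stroke", True)], u_of[("post_stroke", False)]
            )
        cyc_cost["post"][m_pc] += cmed
        util[m_pc] = np.where(recur_chd[m_pc], u_of[("post_chd", True)], u_of[("post_chd", False)])

        # ---- transitions ----
        u_t = uniforms[:, t]
        q_nc = np.zeros(n)
        idx = np.clip(np.floor(age).astype(int), age_min, age_max_tab) - age_min
        q_nc[active] = np.where(
            arrays["is_male"][active], qx_male[idx[active]], qx_female[idx[active]]
        )

        next_state = state.copy()
        died_noncvd = np.zeros(n, dtype=bool)
        died_cvd = np.zeros(n, dtype=bool)
        stroke_event = np.zeros(n, dtype=bool)
        chd_event = np.zeros(n, dtype=bool)
        stroke_ucond = np.zeros(n)

        if m_pre.any():
            lp = arrays["lp_fixed"] + arrays["beta_age"] * (age - arrays["m_age"])
            p10 = np.clip(risk_models.chd_ten_year_risk_vector(lp, np.exp(arrays["log_s10"])), 0.0, _P_CAP)
            p_chd_annual = -np.expm1(np.log1p(-p10) / 10.0)
            choice, u_cond = _hazard_partition(
                [q_nc, np.full(n, p_stroke_by_t[t]), p_chd_annual], u_t
            )
            died_noncvd |= m_pre & (choice == 0)
            fired = m_pre & (choice == 1)
            stroke_event |= fired
            stroke_ucond = np.where(fired, u_cond, stroke_ucond)
            chd_event |= m_pre & (choice == 2)

        for mask, events in (
            (m_s1, ("cvd", rates.mort_stroke_year1, "stroke", rates.stroke_relapse_year1, "chd", rates.chd_after_stroke)),
            (m_c1, ("cvd", rates.mort_chd_year1, "chd", rates.chd_relapse_year1, "stroke", rates.stroke_after_chd)),
            (m_pc, ("cvd", rates.mort_post_chd, "chd", rates.chd_relapse_later, "stroke", rates.stroke_after_post_chd)),
        ):
            if not mask.any():
                continue
            p2 = np.full(n, events[1])
            p3 = np.full(n, events[3])
            p4 = np.full(n, events[5])
            choice, u_cond = _hazard_partition([q_nc, p2, p3, p4], u_t)
            died_noncvd |= mask & (choice == 0)
            died_cvd |= mask & (choice == 1)
            ev3 = mask & (choice == 2)
            ev4 = mask & (choice == 3)
            if events[2] == "stroke":
                stroke_event |= ev3
                stroke_ucond = np.where(ev3, u_cond, stroke_ucond)
            else:
                chd_event |= ev3
            if events[4] == "stroke":
                stroke_event |= ev4
                stroke_ucond = np.where(ev4, u_cond, stroke_ucond)
            else:
                chd_event |= ev4

        if m_ps.any():
            p_rel = rel_sched[np.clip(ys, 0, len(rel_sched) - 1)]
            choice, u_cond = _hazard_partition(
                [q_nc, np.full(n, rates.mort_post_stroke), p_rel, np.full(n, rates.chd_after_post_stroke)],
                u_t,
            )
            died_noncvd |= m_ps & (choice == 0)
            died_cvd |= m_ps & (choice == 1)
            fired = m_ps & (choice == 2)
            stroke_event |= fired
            stroke_ucond = np.where(fired, u_cond, stroke_ucond)
            chd_event |= m_ps & (choice == 3)

        # ---- apply payoffs (half-cycle correction weights the death year) ----
        dying = died_noncvd | died_cvd
        if settings.half_cycle:
            weight[dying] = 0.5
        for c in economics.COST_CATEGORIES:
            cost_cat[c] += d * cyc_cost[c]
            cost_cat_u[c] += cyc_cost[c]
        alive_now = active.astype(float) * weight
        ly += d * alive_now
        ly_u += alive_now
        qaly += d * util * weight
        qaly_u += util * weight

        # ---- commit transitions ----
        counts["noncvd_death"] += int(died_noncvd.sum())
        counts["cvd_death"] += int(died_cvd.sum())
        dead |= dying
        next_state[dying] = 5

        new_stroke = stroke_event & ~dying
        new_chd = chd_event & ~dying
        pre_exit_year[m_pre & (dying | new_stroke | new_chd)] = t
        first = new_stroke & ~had_stroke
        first_stroke_year[first] = t
        counts["first_stroke"] += int(first.sum())
        counts["stroke_total"] += int(new_stroke.sum())
        counts["first_chd"] += int((new_chd & ~had_chd).sum())
        counts["chd_total"] += int(new_chd.sum())

        recur_stroke = np.where(new_stroke, had_stroke, recur_stroke)
        had_stroke |= new_stroke
        subtype = np.where(new_stroke, np.where(stroke_ucond < p_isch, 1, 2), subtype)
        next_state[new_stroke] = 1
        ys = np.where(new_stroke, 1, ys)

        recur_chd = np.where(new_chd, had_chd, recur_chd)
        had_chd |= new_chd
        next_state[new_chd] = 2
        ys = np.where(new_chd, 1, ys)

        quiet = active & ~dying & ~new_stroke & ~new_chd
        tunnel_s = quiet & (state == 1)
        tunnel_c = quiet & (state == 2)
        next_state[tunnel_s] = 3
        next_state[tunnel_c] = 4
        ys = np.where(tunnel_s | tunnel_c, 2, ys)
        aging_post = quiet & ((state == 3) | (state == 4))
        ys = np.where(aging_post, ys + 1, ys)

        state = next_state

    pre_exit_year[pre_exit_year == -1] = t_max  # under observation throughout
    result = economics.ArmResult.from_arrays(
        arm=arm,
        cost_by_cat=cost_cat,
        cost_by_cat_undisc=cost_cat_u,
        ly=ly,
        qaly=qaly,
        ly_undisc=ly_u,
        qaly_undisc=qaly_u,
        event_counts=counts,
        first_stroke_year=first_stroke_year,
    )
    result.pre_exit_year = pre_exit_year
    return result


def run_cohort(
    cohort: Cohort,
    params: ParameterSet,
    settings: SimulationSettings,
) -> tuple[economics.ArmResult, economics.ArmResult]:
    """Simulate both arms over the cohort and return (folic, control) results.

    With ``paired_arms`` (the default) both arms share the run's uniform
    matrix — common random numbers — so incremental outcomes are low-variance
    and a null effect (HR = 1, identical parameters) yields exactly zero
    increments.
    """
    if len(cohort) < 1:
        raise ValueError("cohort must be nonempty")
    max_age = settings.resolve_max_age(params)
    t_max = max(int(math.ceil(max_age - cohort.table["age"].min())), 1)
    if settings.max_years is not None:
        t_max = min(t_max, settings.max_years)
    if settings.paired_arms:
        shared = uniform_matrix(len(cohort), t_max, settings.seed)
        folic = run_arm(cohort, params, settings, "folic", uniforms=shared)
        control = run_arm(cohort, params, settings, "control", uniforms=shared)
    else:
        folic = run_arm(
            cohort, params, settings, "folic", uniforms=uniform_matrix(len(cohort), t_max, settings.seed)
        )
        control = run_arm(
            cohort,
            params,
            settings,
            "control",
            uniforms=uniform_matrix(len(cohort), t_max, settings.seed + 1),
        )
    return folic, control
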