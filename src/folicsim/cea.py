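"""Incremental cost-effectiveness measures and willingness-to-pay classification.

The decision rule follows the WHO-CHOICE GDP-per-capita convention: a strategy
is *highly cost-effective* if its ICER is below 1x GDP per capita per QALY,
*cost-effective* below 3x, and *not cost-effective* otherwise (strict
inequalities; an ICER exactly at a threshold falls in the cheaper tier).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .economics import ArmResult

__all__ = ["CEResult", "icer", "nmb", "classify", "in_trial_worked_example"]


@dataclass
class CEResult:
    """Incremental comparison of two strategies (a vs b, usually folic vs control).

    ``icer`` is defined only when the increments share a sign and the effect
    increment is nonzero; otherwise ``dominance`` carries the tag
    (``dominant`` = cheaper and more effective, ``dominated`` = costlier and
    less effective, ``indifferent`` = both increments zero).
    """

    delta_cost: float
    delta_effect: float
    effect_kind: str  # qaly | ly
    icer: float | None
    dominance: str | None
    se_delta_cost: float = 0.0
    se_delta_effect: float = 0.0

    def nmb(self, wtp: float) -> float:
        return nmb(self, wtp)

    def to_json_dict(self, exchange_rate: float | None = None) -> dict:
        out = {
            "delta_cost_usd": self.delta_cost,
            "delta_effect": self.delta_effect,
            "effect_kind": self.effect_kind,
            "icer_usd": self.icer,
            "dominance": self.dominance,
            "se_delta_cost": self.se_delta_cost,
            "se_delta_effect": self.se_delta_effect,
        }
        if exchange_rate and self.icer is not None:
            out["icer_rmb"] = self.icer * exchange_rate
        return out


def _paired_se(a: ArmResult, b: ArmResult, key: str) -> float:
    pa, pb = a.per_patient.get(key), b.per_patient.get(key)
    if pa is None or pb is None or len(pa) != len(pb) or len(pa) < 2:
        return float("nan")
    diff = pa - pb
    return float(diff.std(ddof=1) / np.sqrt(len(diff)))


def icer(a: ArmResult, b: ArmResult, effect_kind: str = "qaly") -> CEResult:
    """Incremental cost-effectiveness of strategy ``a`` relative to ``b``.

    Both results must come from runs with the same discounting and horizon
    (checked via cohort size as a proxy for paired runs). Effects are the
    discounted QALYs or life-years.
    """
    if effect_kind not in ("qaly", "ly"):
        raise ValueError(f"effect_kind must be 'qaly' or 'ly', got {effect_kind!r}")
    if a.n != b.n:
        raise ValueError(f"arm results sized {a.n} vs {b.n}; compare paired runs")
    dc = a.cost - b.cost
    de = (a.qalys - b.qalys) if effect_kind == "qaly" else (a.life_years - b.life_years)
    se_de = _paired_se(a, b, "qalys" if effect_kind == "qaly" else "life_years")
    ratio: float | None = None
    tag: str | None = None
    if dc == 0.0 and de == 0.0:
        tag = "indifferent"
    elif de > 0 and dc <= 0:
        tag = "dominant"
    elif de < 0 and dc >= 0:
        tag = "dominated"
    elif de == 0.0:
        tag = "dominated" if dc > 0 else "dominant"
    else:
        ratio = dc / de
    return CEResult(
        delta_cost=dc,
        delta_effect=de,
        effect_kind=effect_kind,
        icer=ratio,
        dominance=tag,
        se_delta_cost=_paired_se(a, b, "cost"),
        se_delta_effect=se_de,
    )


def nmb(ce: CEResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * delta_effect - delta_cost`` at a WTP."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * ce.delta_effect - ce.delta_cost


def classify(ce: CEResult, gdp: float) -> str:
    """WHO-CHOICE classification at the 1x / 3x GDP-per-capita thresholds."""
    if gdp <= 0:
        raise ValueError(f"gdp must be > 0, got {gdp}")
    if ce.dominance in ("dominant", "dominated"):
        return ce.dominance
    if ce.dominance == "indifferent":
        return "indifferent"
    assert ce.icer is not None
    if ce.icer < gdp:
        return "highly_cost_effective"
    if ce.icer < 3 * gdp:
        return "cost_effective"
    return "not_cost_effective"


def in_trial_worked_example(path: str | Path | None = None) -> dict:
    """ICER recomputed from the published in-trial aggregate table.

    The trial-period piggyback analysis is out of the simulation's scope; its
    printed per-person aggregates (total costs and QALYs per arm, and their
    differences) ship as package data, and the ICER is recomputed from them
    as incremental cost / incremental QALYs.
    """
    if path is None:
        path = Path(str(resources.files("folicsim.data").joinpath("trial_summary.csv")))
    rows: dict[str, dict[str, float | None]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows[rec["outcome"]] = {
                k: (float(rec[k]) if rec[k] != "" else None) for k in ("folic", "control", "delta")
            }
    delta_cost = rows["total_cost"]["delta"]
    delta_qaly = rows["qaly"]["delta"]
    assert delta_cost is not None and delta_qaly is not None
    return {
        "delta_cost": delta_cost,
        "delta_qaly": delta_qaly,
        "icer_per_qaly": delta_cost / delta_qaly,
        "table": rows,
    }
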