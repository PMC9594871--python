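"""Synthetic baseline cohorts with the trial population's marginal structure.

Patient-level data from the source trial are unavailable, so cohorts are
generated from the printed baseline distributions: age ~ Normal(60, 7.53),
41% male, total cholesterol ~ Normal(213.6, 46) mg/dL, HDL-C ~ Normal(52, 14)
mg/dL, SBP ~ Normal(139.7, 11.1) mmHg, 23% smokers, 3% diabetic. Only
marginals are published, so risk factors are sampled independently by default
(an explicit, documented assumption); normals are truncated at +/- 4 SD and at
hard plausibility floors. MTHFR genotype, folate, and homocysteine use
documented placeholder marginals and serve subgroup routing only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .parameters import ConfigurationError, ParameterSet, SubgroupSpec

__all__ = ["Patient", "Cohort", "generate_cohort", "filter_subgroup"]

#: column order of the cohort table (and its CSV serialization)
COLUMNS = [
    "id",
    "age",
    "sex",
    "sbp",
    "total_chol",
    "hdl_c",
    "smoker",
    "diabetes",
    "mthfr",
    "folate",
    "homocysteine",
]

# hard plausibility floors applied after +/-4 SD truncation
_FLOORS = {"age": 18.0, "sbp": 60.0, "total_chol": 50.0, "hdl_c": 10.0}


@dataclass(frozen=True)
class Patient:
    """One simulated individual at model entry (treatment arm assigned at run time)."""

    id: int
    age: float
    sex: str
    sbp: float
    total_chol: float
    hdl_c: float
    smoker: bool
    diabetes: bool
    mthfr: str
    folate: float
    homocysteine: float
    arm: str | None = None


@dataclass
class Cohort:
    """An ordered collection of patients, held as a DataFrame for speed."""

    table: pd.DataFrame
    seed: int | None = None
    source_spec: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.patients())

    def patients(self) -> list[Patient]:
        return [
            Patient(**{k: rec[k] for k in COLUMNS})
            for rec in self.table.to_dict("records")
        ]

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort (deterministic byte layout) plus a seed sidecar."""
        self.table.to_csv(path, index=False, float_format="%.17g")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"seed": self.seed, "n": len(self), "source_spec": self.source_spec})
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        table = pd.read_csv(path)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(table=table[COLUMNS], seed=meta.get("seed"), source_spec=meta.get("source_spec", {}))


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, k: float, floor: float | None
) -> np.ndarray:
    """Normal draws with out-of-bounds values redrawn (bounds: +/- k SD and floor)."""
    lo, hi = mean - k * sd, mean + k * sd
    if floor is not None:
        lo = max(lo, floor)
    x = rng.normal(mean, sd, size=n)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def generate_cohort(n: int, params: ParameterSet, seed: int = 0) -> Cohort:
    """Sample a baseline cohort of ``n`` patients, deterministic given ``seed``.

    Subgroup-specific refits are supported by overriding the distribution
    moments through ``SubgroupSpec.population`` (applied via
    :func:`folicsim.parameters.perturb` on ``population.*`` paths) before
    calling this function.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    pop = params.population
    k = pop.truncation_sd
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, n, pop.age_mean, pop.age_sd, k, _FLOORS["age"])
    sex = np.where(rng.random(n) < pop.prop_male, "male", "female")
    tc = _truncated_normal(rng, n, pop.total_chol_mean, pop.total_chol_sd, k, _FLOORS["total_chol"])
    hdl = _truncated_normal(rng, n, pop.hdl_c_mean, pop.hdl_c_sd, k, _FLOORS["hdl_c"])
    sbp = _truncated_normal(rng, n, pop.sbp_mean, pop.sbp_sd, k, _FLOORS["sbp"])
    smoker = rng.random(n) < pop.prop_smoker
    diabetes = rng.random(n) < pop.prop_diabetes
    genotypes = sorted(pop.mthfr_probs)
    mthfr = rng.choice(genotypes, size=n, p=[pop.mthfr_probs[g] for g in genotypes])
    folate = np.exp(rng.normal(np.log(pop.folate_log_median), pop.folate_log_sigma, size=n))
    homocysteine = np.exp(
        rng.normal(np.log(pop.homocysteine_log_median), pop.homocysteine_log_sigma, size=n)
    )
    table = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age": age,
            "sex": sex,
            "sbp": sbp,
            "total_chol": tc,
            "hdl_c": hdl,
            "smoker": smoker,
            "diabetes": diabetes,
            "mthfr": mthfr,
            "folate": folate,
            "homocysteine": homocysteine,
        }
    )[COLUMNS]
    spec = {
        "age": [pop.age_mean, pop.age_sd],
        "prop_male": pop.prop_male,
        "total_chol": [pop.total_chol_mean, pop.total_chol_sd],
        "hdl_c": [pop.hdl_c_mean, pop.hdl_c_sd],
        "sbp": [pop.sbp_mean, pop.sbp_sd],
        "prop_smoker": pop.prop_smoker,
        "prop_diabetes": pop.prop_diabetes,
    }
    return Cohort(table=table, seed=seed, source_spec=spec)


def filter_subgroup(cohort: Cohort, spec: SubgroupSpec | str | Callable) -> Cohort:
    """Members of the cohort satisfying a subgroup predicate, order preserved.

    The predicate is a boolean expression over patient fields (``"sex ==
    'male'"``, ``"age >= 55 and age < 65"``), a callable over the cohort
    table, or a full :class:`SubgroupSpec`.
    """
    if isinstance(spec, SubgroupSpec):
        predicate = spec.predicate
    else:
        predicate = spec
    if callable(predicate):
        mask = np.asarray(predicate(cohort.table), dtype=bool)
    else:
        try:
            mask = cohort.table.eval(predicate, engine="python")
        except (ValueError, KeyError, pd.errors.UndefinedVariableError) as exc:
            raise ConfigurationError(
                f"subgroup predicate {predicate!r} references unknown fields "
                f"or is malformed: {exc}"
            ) from exc
        mask = np.asarray(mask, dtype=bool)
    table = cohort.table.loc[mask].reset_index(drop=True)
    return Cohort(table=table, seed=cohort.seed, source_spec=dict(cohort.source_spec, predicate=str(predicate)))
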