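import numpy as np
import pytest

from folicsim.parameters import LifeTable, default_parameters


@pytest.fixture(scope="session")
def params():
    """The packaged base case (treat as read-only; copy before mutating)."""
    return default_parameters()


@pytest.fixture()
def null_params(params):
    """A parameter set in which no transition can fire: zero-hazard world."""
    p = params.copy()
    p.weibull.scale = 1e-300  # numerically zero stroke hazard (scale must stay > 0)
    for name in p.rates._PROBS:
        setattr(p.rates, name, 0.0)
    n = p.life_table.age_max - p.life_table.age_min + 1
    p.life_table = LifeTable(
        age_min=p.life_table.age_min,
        age_max=p.life_table.age_max,
        qx_male=[0.0] * n,
        qx_female=[0.0] * n,
    )
    for m in p.chd_models.values():
        m.baseline_survival_10y = 1.0  # zero 10-year CHD risk
    return p.validate()


@pytest.fixture()
def equal_arm_params(params):
    """Both arms identical: HR = 1 and the same drug price / adherence."""
    p = params.copy()
    p.effect.hazard_ratio = 1.0
    p.effect.ci_high = 1.0
    p.costs.drug_unit_prices["enalapril_folic"] = p.costs.drug_unit_prices["enalapril"]
    p.behavior.adherence_folic = p.behavior.adherence_enalapril
    return p.validate()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220)
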