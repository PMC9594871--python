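"""One-way sensitivity analysis on the most influential parameters.

Each parameter moves to its published lower and upper bound with everything
else at base, under a fixed cohort and random stream; the spread of the two
ICERs is the tornado bar. The stroke hazard ratio dominates.
"""

from folicsim import default_parameters
from folicsim.engine import SimulationSettings
from folicsim.uncertainty import one_way_sa

params = default_parameters()
entries = one_way_sa(
    params,
    SimulationSettings(n_patients=10_000, seed=1),
    parameters=[
        "effect.hazard_ratio",
        "econ.discount_rate",
        "behavior.adherence_folic",
        "behavior.disability_rate",
        "costs.drug_unit_prices.enalapril_folic",
        "utilities.pre_cvd",
    ],
)
print(f"{'parameter':<42}{'ICER @low':>12}{'ICER @high':>12}{'bar width':>12}")
for e in entries:
    print(f"{e.parameter:<42}{e.icer_low:>12,.0f}{e.icer_high:>12,.0f}{e.width:>12,.0f}")
# Bars are sorted by width: the hazard ratio for first stroke swings the ICER
# by far the most, matching the qualitative headline of the analysis.
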