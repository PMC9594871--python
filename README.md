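# folicsim

A patient-level microsimulation model of the lifetime cost-effectiveness of
**enalapril–folic acid versus enalapril alone for primary stroke prevention
in hypertensive patients**, from the Chinese healthcare-sector perspective.

Adding 0.8 mg of folic acid to enalapril reduced the hazard of first stroke
in hypertensive adults (hazard ratio 0.79, 95% CI 0.68–0.93) in a large
randomized trial. Whether that protection is worth paying for is a
health-economic question: the combination pill costs roughly eight times the
enalapril price per day, while each averted stroke avoids hospitalization,
rehabilitation and long-term disability costs and preserves quality-adjusted
life-years. `folicsim` is for health-economics researchers and students who
want a fully inspectable, scriptable implementation of that trade-off: a
discrete annual-cycle, individual-level state-transition model with its
deterministic and probabilistic sensitivity analyses, scenario analyses, and
subgroup machinery.

## The model

Each simulated patient moves through six health states in 1-year cycles:

```
pre-CVD ──► stroke (year-1 tunnel) ──► post-stroke ──┐
   │   └──► CHD    (year-1 tunnel) ──► post-CHD   ───┼──► death (absorbing)
   └─────────────────────────────────────────────────┘
```

* **First stroke** follows a Weibull hazard, S(t) = exp(−λ·t^γ), converted to
  an annual probability `1 − exp[λ·t^γ − λ·(t+1)^γ]`; the treatment arm
  scales it through the proportional-hazards transform `1 − (1 − p)^HR`.
* **First CHD** uses a sex-specific 10-year risk equation
  `P = 1 − S₁₀^exp(Σ βᵢ(xᵢ − Mᵢ))` over age, SBP, total cholesterol, HDL-C,
  diabetes and smoking, annualized as `1 − exp(ln(1 − P)/10)`.
* Recurrence, cross-event, and CVD-mortality probabilities are fixed annual
  rates by state and year since the event; non-CVD mortality comes from an
  age/sex life table. Competing events within a cycle are resolved order-free
  by hazard-proportional allocation of a single uniform draw.
* Costs (drug × adherence, 30-day event costs, rehabilitation/disability,
  post-CVD medication) and state utilities accumulate per cycle, discounted
  at 5%/year; both arms share random streams (common random numbers), so
  incremental quantities are low-noise.
* Cost-effectiveness is summarized as ICER = ΔC/ΔE per QALY and per
  life-year, classified against WHO-CHOICE thresholds (1× and 3× GDP per
  capita, $12,544 in 2021).

Two inputs are not published in the main analysis text and ship as editable,
clearly labelled files: the Weibull calibration target
(`data/stroke_targets_synthetic.csv`) and the CHD equation coefficients
(`data/chd_model_synthetic.csv`, synthetic placeholders). Absolute lifetime
results shift with these inputs; all structural and incremental properties
do not.

## Worked example

```python
from folicsim import cea, default_parameters, generate_cohort, run_cohort
from folicsim.engine import SimulationSettings

params = default_parameters()                      # the packaged base case
cohort = generate_cohort(20_000, params, seed=1)   # synthetic trial-like cohort
folic, control = run_cohort(cohort, params, SimulationSettings(n_patients=20_000, seed=1))
ce = cea.icer(folic, control, "qaly")
print(ce.delta_cost, ce.delta_effect, ce.icer)
```

Running `python examples/01_base_case.py` prints:

```
  folic: cost $ 3493.20  QALYs 10.376  LY 11.650 (undiscounted 19.14)
control: cost $ 1962.79  QALYs 10.308  LY 11.606 (undiscounted 19.03)

incremental cost  $1530.41 (9871.14 RMB)
incremental QALYs 0.0676, incremental LYs 0.0445
ICER  $22,649.91/QALY   $34,411.00/LY
classification at GDP/capita $12,544: cost_effective
```

Adding folic acid costs about $1,530 more per patient over a lifetime and
buys ~0.07 quality-adjusted life-years, i.e. ≈$22.6k per QALY — between 1×
and 3× GDP per capita, hence "cost-effective" but not "highly
cost-effective". The `examples/` directory walks through each capability:
scenarios (`02`), the tornado diagram (`03`), the probabilistic sensitivity
analysis and CEAC (`04`), subgroups (`05`), and Weibull calibration with
internal validation (`06`).

A thin CLI wraps the same library calls:

```bash
folicsim run --n 20000 --seed 1 --scenario half_price --outdir out/
folicsim psa --psa-outer 1000 --psa-inner 2000 --outdir out/
folicsim tornado --outdir out/ && folicsim plot --outdir out/
```

## Configuration

Every parameter of the model — baseline risk-factor distributions,
transition rates, costs, utilities, adherence, discount rate, and the
per-parameter uncertainty distributions used by the sensitivity analyses —
lives in a YAML config (`src/folicsim/data/base_case.yaml` is the packaged
base case). A config file supplies any subset of fields; the rest fall back
to the defaults. `life_table_csv` and `chd_model_csv` keys point at override
CSVs for the life table and CHD equation. See `docs/methods.md` for the
modeling assumptions, parameter provenance, and known limitations.
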