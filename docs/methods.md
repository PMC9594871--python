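# Methods

## Model structure

`folicsim` is a discrete-time, individual-level state-transition
(microsimulation) model with a 1-year cycle and six health states: pre-CVD,
stroke (first-year tunnel), CHD (first-year tunnel), post-stroke, post-CHD,
and death. Tunnel states are occupied for exactly one cycle unless death or a
relapse (which re-enters the tunnel) intervenes; death is absorbing. Payoffs
(costs, utilities, life-years) accrue on whole cycles for the state occupied
during the cycle; transitions are applied at cycle end, so an event drawn in
cycle *t* places the patient in the event-year state during cycle *t* + 1.
The horizon is lifetime, capped at age 100 (config `econ.lifetime_max_age`):
survival beyond the cap is censored, and mortality at the top of the life
table makes that mass negligible.

### Transition probabilities

* **First stroke** (from pre-CVD): Weibull hazard with survival
  S(t) = exp(−λ t^γ) in years since model entry, converted to the annual
  probability 1 − S(t+1)/S(t). The treatment arm applies the hazard ratio via
  the survival-power transform 1 − (1 − p)^HR, which is exact under
  proportional hazards for per-cycle probabilities; a multiplicative p·HR
  differs only at second order at these magnitudes. The benefit-duration
  parameter caps the years over which the HR applies (infinite in the base
  case; 5 or 10 in the scenario analyses).
* **First CHD** (from pre-CVD): sex-specific 10-year risk
  P = 1 − S₁₀^exp(Σᵢ βᵢ(xᵢ − Mᵢ)) over age, systolic blood pressure, total
  cholesterol, HDL-C, diabetes, and current smoking, annualized with equal
  yearly hazard as 1 − exp(ln(1 − P)/10). Risk factors other than age are
  frozen at baseline; age advances yearly and re-enters the equation. Both
  arms share CHD risk (the trial found no arm difference).
* **Recurrence / cross events / CVD death**: fixed annual probabilities per
  state (stroke relapse 17% in the event year; 2–9% afterwards, implemented
  as a piecewise-linear schedule from 9% in year 2 down to 2% at year 10 and
  beyond, since only the range is published; CHD relapse 2.5%/1.2%;
  stroke↔CHD cross rates 0.4%; CVD mortality 15%/3% after stroke, 2.8%/1.5%
  after CHD).
* **Non-CVD mortality**: age/sex life-table lookup. Only the per-mille range
  1.68–507.28‰ is published, so the packaged table is a synthetic Gompertz
  curve q(a) = A·exp(B·a) over ages 35–100 anchored exactly to those bounds,
  identical for both sexes, and overridable by a user CSV (`life_table_csv`).

### Competing events within a cycle

The source analysis does not define an event ordering. Each cycle resolves
all competing transitions with a single uniform draw: the per-event annual
probabilities pᵢ become hazards hᵢ = −ln(1 − pᵢ); the total event probability
1 − exp(−Σhᵢ) is allocated to events proportionally to hᵢ; the uniform is
compared to the resulting partition of [0, 1). This is order-free,
reproducible, and makes simultaneous CVD/non-CVD death impossible by
construction. Stroke events are labelled ischemic vs hemorrhagic by rescaling
the uniform within the stroke segment against the configured ischemic share
(`behavior.p_ischemic`, default 0.80 — an explicit assumption, needed only to
pick between the two published 30-day stroke costs).

### Randomness and pairing

A Philox counter-based generator keyed by the run seed fills one
(patient × cycle) uniform matrix per run; entry (i, t) sits at a fixed
counter position, so results are independent of evaluation order. Both arms
share the matrix (common random numbers): with identical parameters in the
two arms, incremental cost and effect are exactly zero, and incremental
estimates at practical cohort sizes are low-variance. The engine has a
scalar reference path (`step` / `simulate_individual`, recording full
trajectories) and a vectorized cohort path used for production runs; the
test suite asserts their per-patient agreement.

## Economics

All computation is in USD; RMB renderings use the fixed 2021 rate of 6.45.
Future costs, life-years and QALYs are discounted at 5%/year (one-way range
0–8%). No half-cycle correction is applied by default, for fidelity to a
whole-cycle model; `SimulationSettings(half_cycle=True)` credits half a
life-year/QALY in the death cycle.

* **Pre-CVD years**: study-drug cost = unit price/day × 365 × arm adherence
  (0.692 / 0.691), plus concomitant medication = Σ class price × 365 × usage
  share. Usage shares are not published per class for the lifetime horizon;
  the default 0.048 per class reproduces the in-trial average of ≈$16.7/year
  and is identical across arms, so concomitants nearly cancel in ΔC (the
  trial found no significant arm difference). Study-drug costing stops at the
  first CVD event, mirroring the in-trial costing rule; post-event medication
  is folded into post-CVD costs.
* **Event year**: the 30-day hospitalization cost of the event type
  (ischemic $1,529.18, hemorrhagic $3,207.55, CHD $4,696.39) plus
  rest-of-first-year sequela costs.
* **Post-stroke years**: expected cost
  rehabilitation_rate × (training months × $200.93 + checking months × $7.91)
  + disability_rate × 12 × $465.12. The month counts per year are not in the
  main text; defaults are 3 training + 9 checking months in the rest of the
  first year and 12 checking months in later years, all config-exposed.
  Disability (0.39) and rehabilitation (0.58) rates enter as expectations
  rather than per-patient draws — the published quantities are rates, and the
  expectation removes pure Monte-Carlo noise from ΔC without changing means.
* **Post-CHD years**: a configurable annual medication cost, default
  $58.40/year (antiplatelet + lipid-lowering + β-blocker daily prices × 365).
* **Utilities**: pre-CVD 0.90; first/recurrent stroke year 0.76/0.30;
  post-stroke 0.79/0.33; first/recurrent CHD year 0.77/0.64; post-CHD
  0.89/0.76; death 0. "Recurrent" means any second event of that type,
  whatever the path.

ICERs are ΔC/ΔE per QALY and per life-year; when the increments disagree in
sign the result carries a dominance tag instead of a ratio. Classification
follows WHO-CHOICE GDP-per-capita multiples (GDP $12,544; WTP 3× ≈ $37,663)
with strict inequalities: an ICER exactly at a threshold falls in the
cheaper tier. Reported life-year *totals* are undiscounted (lifetime life
expectancy), while LY-denominated ICERs use discounted increments; both
flavors are in `ArmResult`.

## Parameter uncertainty

Each uncertain parameter carries a distribution family, base value, and
range (and sometimes an SD) in `ParameterSet.uncertainty`:

* probabilities, utilities, adherence, disability/rehabilitation rates:
  **beta** — moment-matched to (base, printed SD) on (0, 1) when an SD is
  published (pre-CVD utility SD 0.12, post-CHD utility SD 0.17), otherwise
  moment-matched on the bounded support [low, high] with SD
  (high − low)/3.92, the standard range-to-SD convention;
* costs: **gamma** on (0, ∞), moment-matched to (base, range-implied SD);
* the stroke hazard ratio: **log-normal** with σ implied by the 95% CI
  (0.68–0.93). A beta cannot represent ratios above 1 and the CI is the only
  published dispersion, so the log-normal is the default; the family is
  config-switchable like every other entry;
* the discount rate: varied 0–8% in the one-way analysis, held fixed in the
  PSA.

The **tornado** analysis runs each parameter at its two bounds with
everything else at base, fixed cohort and fixed uniforms, and sorts by bar
width. The **PSA** redraws all uncertain parameters jointly per replicate
(default 1,000 replicates × 2,000 paired patients) on one fixed baseline
cohort with the transition-uniform stream also shared across replicates:
replicates then differ only through parameters, which isolates parameter
uncertainty from Monte-Carlo noise and makes a degenerate (all-fixed)
specification yield identical replicates. Antithetic variates are not used;
CRN pairing alone proved sufficient at these sizes. The CEAC evaluates
P(NMB > 0) over a WTP grid of 0–5× GDP in 101 points.

`find_hr_threshold` bisects the hazard ratio between the CI lower bound and
1 for the point where the ICER crosses a WTP threshold, with a fixed
50,000-patient cohort and fixed uniforms so ICER(HR) is effectively
deterministic and monotone.

**Scenarios** transform the base case: a drug-price multiplier on the
combination pill (the half-price patient-aid-program scenario also rescales
that price's uncertainty spec, so in-scenario PSA draws vary around the
discounted price) and benefit-duration caps of 5 or 10 years. Under CRN a
price change leaves ΔQALY bit-identical and shifts ΔC by exactly the
discounted folic-arm drug saving — an exact invariant the tests assert.

**Subgroups** filter the cohort by a predicate over baseline fields and may
override the Weibull, the hazard ratio, and the baseline distribution
moments (per-subgroup refits); all other parameters stay at base.

## Synthetic population

Patient-level trial data are unavailable, so cohorts are sampled from the
published marginals: age ~ N(60, 7.53), 41% male, total cholesterol
~ N(213.6, 46) mg/dL, HDL-C ~ N(52, 14) mg/dL, SBP ~ N(139.7, 11.1) mmHg,
23% smokers, 3% diabetic. Only marginals are published, so factors are
independent by default — a documented assumption; correlated draws can be
layered on by the user. Normals are truncated at ±4 SD (plus hard
plausibility floors), which leaves moments essentially unchanged while
excluding impossible values. MTHFR genotype (uniform), folate and
homocysteine (log-normal, medians 8 ng/mL and 13 µmol/L) are placeholders
used only for subgroup routing, never in base-case transition math. The
generator reproduces configured moments to Monte-Carlo error and is
byte-stable given a seed.

What passing tests therefore show: the model machinery — formulas,
accounting, pairing, sensitivity analyses — is correct on a population with
the trial's marginal structure. What they do not show: behavior under the
real joint covariance of risk factors, site structure, or any time trend in
event rates.

## Externally sourced inputs

Two quantitative inputs of the original analysis are not in its main text:

* the base-case Weibull (λ, γ) — supplementary material. The package fits
  them at load time from an editable target CSV; the shipped target is the
  single point (4.5 years, 3.4% control-arm cumulative first-stroke
  incidence, the trial's published control event rate) with γ fixed at 1,
  giving λ = −ln(0.966)/4.5 ≈ 0.0076870. Multi-point targets use the
  general least-squares fitter.
* the CHD risk-equation coefficients — published in the equation's source
  cohort study. `data/chd_model_synthetic.csv` ships synthetic placeholder
  coefficients (reference means at the trial's baseline means; baseline
  10-year CHD risk 2.0% for men, 1.0% for women) and is fully replaceable
  (`chd_model_csv` config key).

Absolute lifetime costs, QALYs, and ICERs move with these two inputs; every
incremental *property* (null-effect identity, scenario locality and
orderings, threshold monotonicity, calibration round trips) is invariant to
them, which is why the test suite anchors on the properties and brackets the
absolute ICERs only by magnitude.

## Numerical choices

* Annual probabilities are computed with `expm1`/`log1p` forms and capped at
  1 − 10⁻¹² inside the competing-event partition; a probability of exactly 1
  in the scalar path forces its event (first in the fixed order
  non-CVD death, CVD death, relapse, cross event).
* Weibull fitting uses a log-parameterization (positivity by construction);
  a single target point with fixed shape uses the closed form; all-zero
  incidence returns an explicitly degenerate boundary fit rather than a
  Weibull.
* Internal validation estimates modeled first-stroke incidence by a
  product-limit (Kaplan–Meier-type) estimator over the pre-CVD risk set, so
  competing CHD/death exits do not bias the comparison against the net
  Weibull targets.
* Problem sizes: default runs use 20,000–50,000-patient cohorts (incremental
  SEs a few percent of ΔC under CRN), PSAs 1,000 × 2,000, threshold searches
  a 50,000-patient fixed cohort — sizes at which the reported quantities are
  stable to well under the differences that matter for classification.

## Known limitations

* Independent baseline risk factors (no published covariance).
* The first-stroke Weibull clock is time since model entry, not age; age
  dependence of stroke risk enters only through the lifetime horizon and
  non-CVD mortality. With γ = 1 (the shipped single-point calibration) the
  first-stroke hazard is constant.
* The shipped CHD coefficients are placeholders; absolute CHD incidence (and
  with it part of the cost structure) is indicative until a user supplies
  the published equation.
* Rest-of-year and post-CVD cost month-counts, concomitant usage shares, and
  the post-CHD medication cost are assumptions where the supplement is not
  reproduced; all are single config fields.
* No within-year event timing, no time-varying risk factors other than age,
  no societal-perspective costs, and no efficiency frontier beyond the two
  strategies compared.
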