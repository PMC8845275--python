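# Methods

This note documents the model implemented in `diabsim`: its structure,
parameter provenance, numerical conventions, and the design choices made
where the design was genuinely open. Nothing here asserts an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model structure

`diabsim` is a first-order (patient-level) Monte Carlo microsimulation
with annual cycles and a fixed 50-year default horizon, long enough that
nearly all simulated patients die within it. One patient's cycle runs:

1. risk-factor update (first-year treatment effects in cycle 1; progression
   or intensification afterwards),
2. complication/event draws in a fixed order (MI, stroke, CHF, angina,
   PVD, renal failure, amputation; then the microvascular stage chains in
   catalog order; then hypoglycemia counts),
3. mortality draw,
4. utility and cost accrual,
5. end-of-cycle switch evaluation.

Fixing the intra-cycle order is a reproducibility decision — the order is
not identifiable from published model descriptions, and any fixed order
yields a valid competing-risks approximation at annual resolution. At most
one occurrence per acute event type is allowed per cycle; MI and stroke
may recur in later cycles, the other acute events and all stage chains are
absorbing/forward-only.

**Accrual conventions.** Post-event chronic states ("post-MI",
"post-stroke", post-amputation, advanced microvascular stages) begin in
the cycle *after* the event; the event cycle carries the acute event's
disutility and cost. A patient dying in cycle *t* accrues half a cycle of
life-years, state utility and therapy/management/state costs, plus full
event costs and disutilities (`death_accrual: half_cycle`, switchable to
`full_cycle`). Discounting uses exponent 0 for the first cycle, so the
present value of `[1, 1]` at 4% is `1 + 1/1.04`. Both conventions are
unidentifiable from published totals and are fixed for reproducibility.

## Cohort generation

Baseline cohorts reproduce the two published trial populations (mean, SD,
and proportions for age, diabetes duration, sex, HbA1c, SBP, BMI, smoking,
cigarettes/day, alcohol). Continuous characteristics are sampled from
independent truncated normals — age ∈ [18, 100] years, HbA1c ∈ [4, 15] %,
BMI ∈ [15, 70] kg/m², SBP ∈ [80, 220] mmHg, duration ≥ 0 (and ≤ age − 18);
lipids ∈ [80, 400] / [15, 120] mg/dL and eGFR ∈ [15, 200] mL/min/1.73m²
use the same mechanism. Truncation prevents non-physical draws; the bounds
are ≥ 4 SD from every packaged mean, so the induced moment bias is far
below Monte Carlo error. No correlation structure is imposed because none
is published; real trial populations correlate BMI, SBP, lipids and
duration, so joint-tail behaviour (e.g. very obese hypertensive patients)
is underrepresented relative to reality. Baseline total cholesterol, HDL
and eGFR are not published for these cohorts; the packaged defaults
(180 ± 40, 45 ± 12, 90 ± 20) are ordinary values for a type 2 diabetes
population and are flagged as non-source values in the data files.

## Risk-factor progression and treatment switching

HbA1c follows a first-order autoregression toward a duration-dependent
attractor,

    h' = w·h + (1 − w)·(a + b·duration),

the package's stand-in for the unpublished reference progression
equation. It reproduces the two qualitative behaviours that equation is
described as having — HbA1c rises over time, and between-arm differences
shrink (geometrically, factor *w* per year). The packaged defaults
(w = 0.72, a = 7.8 %, b = 0.05 %/year) were calibrated once so that, from
the published baselines and first-year effects with the 7.5% switch
threshold, the cohort mean time on initial therapy rounds to the published
durations: 3 years for oral semaglutide (both comparisons), 3 for
dulaglutide, 2 for empagliflozin. This calibration is part of the study
conditions, not a free parameter; the acceptance suite re-derives the
durations from 10,000-patient runs.

Switching is evaluated per patient at end of cycle with a strict
inequality ("exceeded" 7.5%), takes effect the next cycle, and is
absorbing. The published analysis reports only single per-arm durations,
leaving open whether the original engine switches per-patient or at the
cohort mean; the per-patient rule is the natural choice in a
patient-level model and its cohort mean is what the calibration targets.
The intensification HbA1c response defaults to a linear-in-HbA1c reduction
`max(0, −2.55 + 0.45·h)` (an editable stand-in for the published
multivariate insulin-initiation equations, whose coefficients are not
reproduced here); `target_value` (set to 7.0%) and `none` policies
implement the corresponding sensitivity analyses.

BMI is piecewise-constant: treated value while on initial therapy,
reverted to baseline on intensification (or maintained for life under the
`maintain_lifetime` sensitivity setting). SBP and lipids drift by the same
AR form toward attractors (145 mmHg, 195 mg/dL; HDL held constant) —
gentle, plausible natural-history drifts standing in for the reference
engine's internal algorithms. eGFR is carried but not progressed (no
progression rule is described for it in the source analysis).

## Complication risks and mortality

Macrovascular and terminal events use Weibull proportional hazards on the
diabetes-duration time scale with published-style covariate sets (age at
diagnosis, sex, smoking, HbA1c, SBP/10, lipid ratio, BMI, eGFR) and
centering. The published coefficient values are not reproduced in the
source paper, so the packaged `risk_ukpds68.yaml` / `risk_ukpds82.yaml`
files carry plausible defaults chosen to give realistic lifetime
incidences at the packaged baseline (e.g. annual first-MI risk near 0.5%
at baseline, rising with duration); they are the user-visible control
surface of the risk engine, and every test of the engine is written
against the equation *forms* with hand-set fixtures, so results hold for
any coefficient file a user supplies. Switching between the two sets is a
pure data swap over one code path (property-tested).

Microvascular complications advance along forward-only stage chains
(retinopathy none→BDR→PDR→SVL, nephropathy none→micro→gross→ESRD with a
modality split, neuropathy, foot ulcer with healing, macular edema,
cataract) with annual probabilities optionally scaled by
`rr^(HbA1c − 7)` and gated by flags (neuropathy multiplies ulcer
incidence, retinopathy multiplies macular edema). These tables are
documented plumbing so that every utility-bearing health state is
reachable; they are not estimates of any published sub-model.

Mortality per cycle is `1 − Π(1 − q_i)` over background risk (life-table
lookup), acute case fatalities for the cycle's events, and chronic excess
risks for active states. The packaged life table is **synthetic**
(`life_table_synthetic.yaml`): a Gompertz hazard (male
`q = 7.5e−5·e^{0.0896·age}`, female scaled by 0.6, certain death from age
100) set at a level about 1.6× a general-population table, appropriate
for a diabetes cohort; with the packaged risk equations it yields
discounted life expectancies near 12.5–13 years for the packaged cohorts,
the right scale for this population under 4% discounting.

## Utilities and costs

The utility catalog holds the published health-state utilities and event
disutilities (complication-free baseline 0.785; e.g. post-amputation
0.505, MI event −0.055, nocturnal severe hypoglycemia −0.062, BMI
−0.0061 per kg/m² above 25). Coexisting states combine by **additive
decrements** from baseline, floored at zero — the additive construction
mirrors how the catalog itself was built from baseline plus decrements;
no multi-morbidity combination rule is published. Alternative disutility
models for the sensitivity analyses are catalog entries: a smaller
per-unit BMI slope, an alternative hypoglycemia decrement table, and a
diminishing hypoglycemia model in which the *k*-th lifetime severe event
carries `rho^(k−1)` of the full decrement (rho = 0.8, user-editable; the
original functional form is not published).

Costs accrue into seven lifetime categories (treatment, management,
hypoglycemia, cardiovascular, renal, ophthalmic, neuropathy/foot).
Therapy costs are annualized at 365.25 days/year; basal insulin uses the
40 IU defined daily dose plus one needle and one strip per day. The
packaged cost catalog is a **schema-complete placeholder** — the source
analysis's national tariffs and pharmacy prices are not public — so
absolute cost totals and ICERs under the defaults are illustrative only;
every entry is linear in the catalog's scale factor and replaceable.
A `comparator_price_multiplier` and a complication-cost multiplier
implement the pricing and ±10% cost sensitivity analyses.

## Sensitivity machinery

The deterministic suite contains all 21 published scenario rows as pure
config transformations run under common seeds (horizons 10/20/35/50;
0%/3% discounting; BMI maintained for life; no HbA1c change on switch;
±95% CI of the HbA1c and BMI treatment differences, where the "upper"
bound is the one favouring the intervention; linear progression with
fixed 3-year switching to 7.0%; complication costs ±10%; the alternative
risk-equation set; the three alternative disutility models; comparator
price −10%; significant-differences-only). The key-driver decomposition
applies the intervention's effect differences one at a time with all
other parameters set to the comparator's values.

The PSA draws treatment-effect means from normals on the published SEs,
cohort characteristic means from normals with SE = SD/√400 (a nominal
trial-arm size), cost entries from gammas with CV 20%, and state-utility
decrements from betas with CV 10% — distribution families follow standard
practice for effects/costs/utilities; the original analysis names the
sampled quantities but not its distributions or dimensions. Defaults
(iterations, first-order n per iteration, spreads) are exposed as
arguments; with all spreads zero the second-order draw is the identity
and the PSA collapses onto the deterministic comparison.

## Problem sizes and seeds

One master seed derives named substreams (cohort, per-patient event
streams shared across arms, PSA parameter and first-order streams).
Reported SDs are across first-order patients, matching the
means-(standard-deviations) presentation convention. The acceptance
script uses 10,000-patient lifetime runs for the treatment-duration
targets and 10,000 patient-years/draws for the rate and moment-recovery
targets; the test suite uses 1,500–10,000 patients for calibration and
directional checks and smaller cohorts for structural properties, sizes
chosen so the full suite documents the same behaviour at a few minutes'
runtime.

## What the synthetic layers do and do not show

Passing tests demonstrate that the engine reproduces its published
*inputs* (cohort moments, first-year effects, adverse-event rates,
utilities), the published *dynamics* (treatment durations, the direction
of the main sensitivity analyses), and the internal-consistency
properties of cost-effectiveness accounting. They do not validate the
placeholder cost catalog, the synthetic life table, the stand-in risk
coefficients or transition tables against real-world data, and therefore
do not reproduce the published absolute cost totals, ICERs or PSA
probabilities, which additionally depend on non-public unit costs and on
undisclosed internals of the original proprietary engine. Users applying
the model should substitute jurisdiction-specific tariffs, a national
life table, and transcribed risk-equation coefficients.

## Known limitations

- Baseline characteristics are sampled independently; no correlation
  matrix.
- Annual cycles only; no half-cycle correction beyond the death-year
  convention; no within-year event ordering effects.
- One treatment pathway (initial therapy → basal insulin); no adherence,
  dose titration, or add-on algorithms.
- Cardiovascular-outcome-trial effects are deliberately not modelled,
  matching the source analysis.
- The microvascular transition tables are calibrated for plausibility,
  not estimated from cohort data.
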