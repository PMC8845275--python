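# diabsim

Patient-level microsimulation of long-term cost-effectiveness for
glucose-lowering therapies in type 2 diabetes.

`diabsim` is for health economists and modellers who want an open, testable
implementation of the classic diabetes policy-model workflow: simulate
individual patients through annual cycles of risk-factor progression,
treatment intensification, diabetes-related complications and death, and
aggregate discounted life-years, quality-adjusted life-years (QALYs) and
direct costs into incremental cost-effectiveness ratios (ICERs) and
cost-effectiveness acceptability curves (CEACs).

It ships ready-made configurations for two head-to-head comparisons of
oral semaglutide 14 mg in patients inadequately controlled on oral
antidiabetic drugs — versus empagliflozin 25 mg (52-week trial data,
trial-product estimand) and versus dulaglutide 1.5 mg (network
meta-analysis effects) — with the published baseline cohorts, first-year
treatment effects, and health-state utility catalog.

## Model in brief

Each simulated patient carries risk factors (HbA1c, SBP, lipids, BMI,
eGFR, smoking) and complication states. Per annual cycle *t*:

1. **Progression** — first-year treatment effects in cycle 1; afterwards
   HbA1c follows an autoregression toward a duration-dependent attractor,
   `h_{t+1} = w·h_t + (1−w)(a + b·duration)`, so glycemic control decays
   and between-arm differences shrink geometrically; SBP/lipids drift by
   the same AR form; BMI is piecewise-constant.
2. **Intensification** — once end-of-cycle HbA1c strictly exceeds 7.5%,
   the patient switches to basal insulin (40 IU/day plus one needle and
   one glucose strip per day), HbA1c drops per the configured response,
   BMI reverts to baseline, and hypoglycemia rates rise to 4.08 / 0.10
   events per patient-year (non-severe / severe).
3. **Events** — Weibull proportional-hazards equations on the
   diabetes-duration time scale, `P = 1 − exp(H(t) − H(t+1))` with
   `H(t) = exp(β'x)·t^ρ`, drive macrovascular and terminal events;
   forward-only transition tables drive the microvascular stage chains;
   Poisson draws generate hypoglycemia counts.
4. **Mortality** — life-table background risk, acute case fatality and
   chronic excess risk combine as independent competing risks.
5. **Accounting** — annual utility is the complication-free baseline
   (0.785) minus additive state decrements, event disutilities and a BMI
   decrement (−0.0061 per kg/m² above 25), floored at 0; costs accrue by
   category; both are discounted at 4%/year (first cycle undiscounted).

Both arms of a comparison consume the same sampled cohort and the same
per-patient random streams (common random numbers), so identical arms give
exactly zero deltas and the between-arm differences isolate treatment
effects. A probabilistic sensitivity analysis wraps the first-order engine
in second-order draws of treatment effects (normal on published SEs),
cohort means, costs (gamma) and utilities (beta).

Unit costs are deliberately a **placeholder catalog**
(`make_placeholder_cost_catalog`): the underlying national tariffs are not
public, so absolute cost totals and ICERs from the defaults are
illustrative — replace the catalog with real tariffs for applied work.

## Worked example

```bash
diabsim compare --comparison pioneer2 --seed 42 --n-patients 2000 --out results/
```

prints

```
dQALY +0.0683, dCost +2363, ICER 34609 per QALY
```

i.e. over 2,000 simulated lifetimes, oral semaglutide gained 0.068
discounted QALYs per patient over empagliflozin at an extra (placeholder)
cost of 2,363, giving an ICER of 34,609 per QALY gained. `results/`
contains per-arm outcomes (`arm_outcomes.csv`, with means and patient-level
SDs), the cost breakdown by category (`cost_breakdown.csv`), the
comparison (`comparison.json`) and a run manifest. Other subcommands:
`run` (one arm), `psa` (scatter + CEAC), `scenarios` (the deterministic
sensitivity suite or the key-driver decomposition), `fixtures` (export the
packaged catalogs for editing).

From Python:

```python
import diabsim as d

setup = d.load_study("pioneer2")
sema = d.run_arm(setup, "intervention", seed=1, n_patients=2000)
empa = d.run_arm(setup, "comparator", seed=1, n_patients=2000)
print(sema.mean_years_on_initial)       # ~3 years on oral semaglutide
print(empa.mean_years_on_initial)       # ~2 years on empagliflozin
print(d.compare_arms(sema, empa).icer)
```

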