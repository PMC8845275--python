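"""Annual-cycle Monte Carlo engine, cost-effectiveness outputs and PSA.

The first-order simulation walks each sampled patient through annual cycles
until death or the horizon: first-year treatment effects (cycle 1),
risk-factor progression, complication/event draws, the HbA1c-triggered
switch to basal insulin, utility and cost accrual, and a mortality draw.
Within a comparison both arms consume the same sampled baseline cohort and
the same per-patient random streams (common random numbers), so two arms
with identical effect profiles produce identical outcomes and the
between-arm deltas isolate the treatment effects.

Accrual conventions (configurable): a patient dying in a cycle accrues half
a cycle of life-years, state utility, and therapy/management/state costs,
plus full event costs and disutilities; post-event chronic states begin in
the cycle after the event, while the event cycle itself carries the event
disutility and cost.  Discounting starts at exponent 0 (first cycle
undiscounted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import risk as risk_mod
from .cohort import make_placeholder_cost_catalog, sample_cohort
from .config import (
    CohortSpec,
    LifeTable,
    PatientState,
    SimulationConfig,
    TreatmentEffectProfile,
    active_state_tags,
    load_life_table,
    load_study_config,
)
from .economics import (
    COST_CATEGORIES,
    DiscountedLedger,
    UtilityCatalog,
    _hypo_decrement,
    annual_cost,
    load_utility_catalog,
    state_utility_component,
)
from .progression import (
    apply_first_year_effects,
    apply_intensification,
    progress_hba1c,
    progress_secondary_factors,
)
from .risk import (
    RiskCoefficientSet,
    TransitionTable,
    annual_death_probability,
    sample_cycle_events,
)
from .treatment import CostCatalog, annual_therapy_cost, evaluate_switch

#: complications tracked for cumulative incidence / time-to-onset reporting
TRACKED_COMPLICATIONS = (
    "mi_event",
    "stroke_event",
    "chf_event",
    "angina_event",
    "pvd_event",
    "renal_failure_event",
    "amputation_event",
    "ulcer_event",
)


@dataclass
class StudySetup:
    """Everything one comparison needs: cohort, arm profiles, config, catalogs."""

    comparison: str
    cohort_spec: CohortSpec
    intervention: TreatmentEffectProfile
    comparator: TreatmentEffectProfile
    config: SimulationConfig
    utility_catalog: UtilityCatalog
    cost_catalog: CostCatalog
    risk_sets: dict[str, dict[str, RiskCoefficientSet]]
    transitions: list[TransitionTable]
    mortality: list[RiskCoefficientSet]
    life_table: LifeTable

    def profile(self, arm: str) -> TreatmentEffectProfile:
        if arm in (self.intervention.arm_name, "intervention"):
            return self.intervention
        if arm in (self.comparator.arm_name, "comparator"):
            return self.comparator
        raise ValueError(
            f"unknown arm {arm!r}; have "
            f"{self.intervention.arm_name!r}, {self.comparator.arm_name!r}"
        )

    def copy(self) -> "StudySetup":
        return StudySetup(
            comparison=self.comparison,
            cohort_spec=self.cohort_spec.model_copy(deep=True),
            intervention=self.intervention.model_copy(deep=True),
            comparator=self.comparator.model_copy(deep=True),
            config=self.config.model_copy(deep=True),
            utility_catalog=self.utility_catalog.model_copy(deep=True),
            cost_catalog=self.cost_catalog.model_copy(deep=True),
            risk_sets={k: dict(v) for k, v in self.risk_sets.items()},
            transitions=list(self.transitions),
            mortality=list(self.mortality),
            life_table=self.life_table,
        )


def load_study(comparison: str = "pioneer2", cost_scale: float = 1.0, **config_overrides) -> StudySetup:
    """Assemble a ready-to-run study from the packaged parameter catalogs."""
    cohort_spec, (intervention, comparator), config = load_study_config(comparison)
    if config_overrides:
        config = config.model_copy(update=config_overrides)
    return StudySetup(
        comparison=comparison,
        cohort_spec=cohort_spec,
        intervention=intervention,
        comparator=comparator,
        config=config,
        utility_catalog=load_utility_catalog(),
        cost_catalog=make_placeholder_cost_catalog(cost_scale),
        risk_sets={name: risk_mod.load_risk_set(name) for name in ("ukpds68", "ukpds82")},
        transitions=risk_mod.load_transition_tables(),
        mortality=risk_mod.load_mortality_model(),
        life_table=load_life_table(),
    )


@dataclass
class PatientTrace:
    """Per-cycle record of one simulated patient."""

    ledger: DiscountedLedger
    hba1c: list[float] = dc_field(default_factory=list)
    therapy: list[str] = dc_field(default_factory=list)
    events: list[list[str]] = dc_field(default_factory=list)
    years_on_initial: float = 0.0
    died_cycle: Optional[int] = None
    first_onset: dict[str, int] = dc_field(default_factory=dict)


def simulate_patient(
    patient: PatientState,
    profile: TreatmentEffectProfile,
    config: SimulationConfig,
    setup: StudySetup,
    rng: np.random.Generator,
    is_comparator: bool = False,
) -> PatientTrace:
    """Run one patient from cycle 1 until death or the horizon."""
    equations = setup.risk_sets[config.risk_set]
    ledger = DiscountedLedger(config.discount_rate_costs, config.discount_rate_effects)
    trace = PatientTrace(ledger=ledger)
    pending_switch = False

    for t in range(1, config.horizon_years + 1):
        switched_now = False
        if t == 1:
            apply_first_year_effects(patient, profile)
        else:
            if pending_switch:
                apply_intensification(
                    patient, config.intensification_policy, config.bmi_persistence
                )
                pending_switch = False
                switched_now = True
            if not switched_now:
                progress_hba1c(patient, config.hba1c_law)
            progress_secondary_factors(patient, config.secondary_drift)

        # chronic states active for this cycle's accrual: start-of-cycle snapshot
        pre_tags = active_state_tags(patient)
        on_initial = patient.therapy == "initial"
        if on_initial:
            ns_rate = profile.nonsevere_hypo_rate / 100.0
            sev_rate = profile.severe_hypo_rate / 100.0
        else:
            ns_rate = config.basal_nonsevere_hypo_rate
            sev_rate = config.basal_severe_hypo_rate
        sample_cycle_events(
            patient,
            equations,
            setup.transitions,
            rng,
            nonsevere_hypo_rate=ns_rate,
            severe_hypo_rate=sev_rate,
            nocturnal_fraction_nonsevere=profile.nocturnal_fraction_nonsevere,
            nocturnal_fraction_severe=profile.nocturnal_fraction_severe,
        )
        for tag in patient.events_this_cycle:
            if tag in TRACKED_COMPLICATIONS and tag not in trace.first_onset:
                trace.first_onset[tag] = t

        q_death = annual_death_probability(
            patient, setup.life_table, setup.mortality, patient.events_this_cycle, pre_tags
        )
        dies = rng.random() < q_death
        frac = 0.5 if (dies and config.death_accrual == "half_cycle") else 1.0

        state_u = state_utility_component(
            pre_tags, setup.utility_catalog, bmi=patient.bmi,
            bmi_model=config.utility_model_bmi,
        )
        event_u = sum(
            setup.utility_catalog.event_disutilities.get(tag, 0.0)
            for tag in patient.events_this_cycle
        )
        event_u -= _hypo_decrement(setup.utility_catalog, patient, config.hypo_disutility_model)
        utility = max(0.0, frac * state_u + event_u)

        therapy_cost = annual_therapy_cost(
            patient, setup.cost_catalog, profile.annual_therapy_cost_key, is_comparator
        )
        costs = annual_cost(
            patient,
            setup.cost_catalog,
            therapy_cost,
            complication_cost_multiplier=config.complication_cost_multiplier,
            state_tags=pre_tags,
            state_fraction=frac,
        )
        ledger.record(utility, frac, costs)
        trace.hba1c.append(patient.hba1c)
        trace.therapy.append(patient.therapy)
        trace.events.append(list(patient.events_this_cycle))
        if on_initial:
            trace.years_on_initial += 1.0

        if dies:
            patient.alive = False
            trace.died_cycle = t
            break

        patient.age += 1.0
        patient.duration += 1.0
        patient.years_on_therapy += 1.0
        if config.switch_fixed_year is not None:
            if on_initial and t >= config.switch_fixed_year:
                pending_switch = True
        elif evaluate_switch(patient, config.switch_threshold_hba1c):
            pending_switch = True

    patient.years_on_initial = trace.years_on_initial
    return trace


@dataclass
class ArmOutcome:
    """Aggregated first-order results of one arm (means and patient-level SDs)."""

    arm_name: str
    n_patients: int
    life_years_discounted: float
    life_years_discounted_sd: float
    life_years_undiscounted: float
    qalys_discounted: float
    qalys_discounted_sd: float
    cost_total_discounted: float
    cost_total_discounted_sd: float
    cost_by_category: dict[str, float]
    cumulative_incidence: dict[str, float]
    mean_time_to_onset: dict[str, float]
    mean_years_on_initial: float

    def summary_row(self) -> dict:
        row = {
            "arm": self.arm_name,
            "n": self.n_patients,
            "life_years_disc": self.life_years_discounted,
            "life_years_disc_sd": self.life_years_discounted_sd,
            "life_years_undisc": self.life_years_undiscounted,
            "qalys_disc": self.qalys_discounted,
            "qalys_disc_sd": self.qalys_discounted_sd,
            "cost_disc": self.cost_total_discounted,
            "cost_disc_sd": self.cost_total_discounted_sd,
            "years_on_initial": self.mean_years_on_initial,
        }
        row.update({f"cost_{k}": v for k, v in self.cost_by_category.items()})
        return row


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Per-patient substream shared across arms (common random numbers).
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, 7919, index)))


def run_arm(
    setup: StudySetup,
    arm: str,
    seed: Optional[int] = None,
    n_patients: Optional[int] = None,
    cohort: Optional[Sequence[PatientState]] = None,
) -> ArmOutcome:
    """Simulate one arm over the shared sampled cohort and aggregate outcomes.

    The cohort is drawn from the ``cohort`` substream of ``seed`` and each
    patient's event stream from a per-patient substream, so both arms of a
    comparison see identical baselines and random numbers.
    """
    config = setup.config
    seed = config.seed if seed is None else seed
    n = config.n_patients if n_patients is None else n_patients
    profile = setup.profile(arm)
    is_comparator = profile.arm_name == setup.comparator.arm_name
    if cohort is None:
        cohort_seed = int(np.random.SeedSequence(entropy=(seed, 104729)).generate_state(1)[0] % (2**31))
        cohort = sample_cohort(setup.cohort_spec, n, cohort_seed)
    else:
        n = len(cohort)

    disc_ly = np.empty(n)
    undisc_ly = np.empty(n)
    disc_qaly = np.empty(n)
    disc_cost = np.empty(n)
    cost_cats = {cat: np.empty(n) for cat in COST_CATEGORIES}
    years_initial = np.empty(n)
    incidence = {tag: 0 for tag in TRACKED_COMPLICATIONS}
    onset_sums = {tag: 0.0 for tag in TRACKED_COMPLICATIONS}

    import copy

    for i, base_patient in enumerate(cohort):
        patient = copy.copy(base_patient)
        patient.events_this_cycle = []
        rng = _patient_rng(seed, i)
        trace = simulate_patient(patient, profile, config, setup, rng, is_comparator)
        ledger = trace.ledger
        disc_ly[i] = ledger.discounted_life_years
        undisc_ly[i] = ledger.undiscounted_life_years
        disc_qaly[i] = ledger.discounted_qalys
        costs = ledger.discounted_costs()
        disc_cost[i] = costs["total"]
        for cat in COST_CATEGORIES:
            cost_cats[cat][i] = costs[cat]
        years_initial[i] = trace.years_on_initial
        for tag, cycle in trace.first_onset.items():
            incidence[tag] += 1
            onset_sums[tag] += cycle

    return ArmOutcome(
        arm_name=profile.arm_name,
        n_patients=n,
        life_years_discounted=float(disc_ly.mean()),
        life_years_discounted_sd=float(disc_ly.std(ddof=1)) if n > 1 else 0.0,
        life_years_undiscounted=float(undisc_ly.mean()),
        qalys_discounted=float(disc_qaly.mean()),
        qalys_discounted_sd=float(disc_qaly.std(ddof=1)) if n > 1 else 0.0,
        cost_total_discounted=float(disc_cost.mean()),
        cost_total_discounted_sd=float(disc_cost.std(ddof=1)) if n > 1 else 0.0,
        cost_by_category={cat: float(arr.mean()) for cat, arr in cost_cats.items()},
        cumulative_incidence={tag: incidence[tag] / n for tag in TRACKED_COMPLICATIONS},
        mean_time_to_onset={
            tag: (onset_sums[tag] / incidence[tag]) if incidence[tag] else math.nan
            for tag in TRACKED_COMPLICATIONS
        },
        mean_years_on_initial=float(years_initial.mean()),
    )


# --------------------------------------------------------------------------
# cost-effectiveness comparison
# --------------------------------------------------------------------------


@dataclass
class CEResult:
    """Pairwise cost-effectiveness result: deltas, ICER/dominance, PSA outputs.

    Quadrant conventions: the ICER (cost per QALY gained) is reported when
    ``delta_qaly`` and ``delta_cost`` share a sign away from zero in the
    northeast quadrant; a cheaper-and-better intervention is
    ``intervention_dominant``; a costlier-and-worse one is
    ``comparator_dominant``; ``delta_qaly == 0`` with nonzero cost yields an
    explicit undefined ICER (``icer is None``) with dominance set by the
    cost sign.
    """

    intervention: str
    comparator: str
    delta_qaly: float
    delta_cost: float
    delta_life_years: float
    icer: Optional[float]
    dominance: Optional[str]
    scatter: list[tuple[float, float]] = dc_field(default_factory=list)
    ceac: dict[float, float] = dc_field(default_factory=dict)


def _classify(delta_cost: float, delta_qaly: float) -> tuple[Optional[float], Optional[str]]:
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            return None, None
        return None, "comparator_dominant" if delta_cost > 0 else "intervention_dominant"
    if delta_qaly > 0 and delta_cost <= 0:
        return None, "intervention_dominant"
    if delta_qaly < 0 and delta_cost >= 0:
        return None, "comparator_dominant"
    return delta_cost / delta_qaly, "icer"


def compare_arms(a: ArmOutcome, b: ArmOutcome) -> CEResult:
    """Incremental comparison of intervention ``a`` against comparator ``b``."""
    dq = a.qalys_discounted - b.qalys_discounted
    dc = a.cost_total_discounted - b.cost_total_discounted
    icer, dominance = _classify(dc, dq)
    return CEResult(
        intervention=a.arm_name,
        comparator=b.arm_name,
        delta_qaly=dq,
        delta_cost=dc,
        delta_life_years=a.life_years_discounted - b.life_years_discounted,
        icer=icer,
        dominance=dominance,
    )


def run_comparison(setup: StudySetup, seed: Optional[int] = None, n_patients: Optional[int] = None) -> tuple[ArmOutcome, ArmOutcome, CEResult]:
    """Run both arms with common random numbers and compare them."""
    a = run_arm(setup, "intervention", seed=seed, n_patients=n_patients)
    b = run_arm(setup, "comparator", seed=seed, n_patients=n_patients)
    return a, b, compare_arms(a, b)


def ceac_from_scatter(
    scatter: Sequence[tuple[float, float]], wtp_grid: Sequence[float]
) -> dict[float, float]:
    """CEAC(WTP) = fraction of (delta_cost, delta_qaly) draws with positive net benefit."""
    out = {}
    for wtp in wtp_grid:
        wins = sum(1 for dc, dq in scatter if wtp * dq - dc > 0)
        out[float(wtp)] = wins / len(scatter)
    return out


DEFAULT_WTP_GRID = tuple(range(0, 100_001, 5_000))


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis (second-order Monte Carlo)
# --------------------------------------------------------------------------


def _sample_second_order(
    setup: StudySetup,
    rng: np.random.Generator,
    cost_cv: float = 0.2,
    utility_cv: float = 0.1,
    cohort_n: Optional[int] = 400,
) -> StudySetup:
    """Draw one second-order parameter set: effects, cohort means, costs, utilities.

    Treatment-effect means are drawn normal(mean, SE); cohort characteristic
    means normal(mean, sd/sqrt(cohort_n)) (a nominal trial-arm size,
    ``None`` disables); cost entries gamma with sd = ``cost_cv`` x mean;
    state-utility decrements beta-rescaled on [0, baseline] with
    sd = ``utility_cv`` x decrement.  With all spreads zero (and zero
    effect SEs) the draw is the identity and the PSA collapses onto the
    deterministic comparison.
    """
    s = setup.copy()
    for profile in (s.intervention, s.comparator):
        for name in ("delta_hba1c", "delta_sbp", "delta_tc", "delta_hdl", "delta_bmi", "delta_egfr"):
            eff = getattr(profile, name)
            if eff.se > 0:
                eff.mean = float(rng.normal(eff.mean, eff.se))
    if cohort_n:
        spec = s.cohort_spec
        for name in ("start_age", "diabetes_duration", "hba1c", "sbp", "bmi",
                     "total_cholesterol", "hdl", "egfr"):
            dist = getattr(spec, name)
            if dist.sd > 0:
                dist.mean = float(rng.normal(dist.mean, dist.sd / math.sqrt(cohort_n)))

    if cost_cv > 0:
        cat = s.cost_catalog
        shape = 1.0 / cost_cv**2
        for mapping in (cat.event_costs, cat.state_annual_costs):
            for key, mean in mapping.items():
                if mean > 0:
                    mapping[key] = float(rng.gamma(shape, mean / shape))
        if cat.management_annual_cost > 0:
            cat.management_annual_cost = float(
                rng.gamma(shape, cat.management_annual_cost / shape)
            )

    if utility_cv > 0:
        ucat = s.utility_catalog
        base = ucat.baseline_utility
        for tag, u in list(ucat.state_utilities.items()):
            dec = base - u
            if dec <= 0:
                continue
            sd = utility_cv * dec
            mean_frac = dec / base
            var_frac = (sd / base) ** 2
            common = mean_frac * (1 - mean_frac) / var_frac - 1.0
            if common <= 0:
                continue
            alpha, beta = mean_frac * common, (1 - mean_frac) * common
            ucat.state_utilities[tag] = base * (1.0 - float(rng.beta(alpha, beta)))
    return s


def run_psa(
    setup: StudySetup,
    n_iterations: int = 200,
    n_patients: int = 250,
    seed: int = 1,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    cost_cv: float = 0.2,
    utility_cv: float = 0.1,
    cohort_n: Optional[int] = 400,
) -> CEResult:
    """Second-order Monte Carlo over parameter uncertainty.

    Each iteration draws a parameter set, runs a reduced-size first-order
    simulation per arm with common random numbers, and records the
    (delta cost, delta QALY) pair; the CEAC is the fraction of iterations
    with positive net monetary benefit at each willingness-to-pay value.
    """
    if n_iterations < 2:
        raise ValueError("PSA needs at least 2 iterations")
    master = np.random.SeedSequence(entropy=(seed, 424243))
    param_rng = np.random.default_rng(master)
    scatter: list[tuple[float, float]] = []
    dq_sum = dcost_sum = dly_sum = 0.0
    for it in range(n_iterations):
        drawn = _sample_second_order(setup, param_rng, cost_cv, utility_cv, cohort_n)
        fo_seed = int(np.random.SeedSequence(entropy=(seed, 31337, it)).generate_state(1)[0] % (2**31))
        a = run_arm(drawn, "intervention", seed=fo_seed, n_patients=n_patients)
        b = run_arm(drawn, "comparator", seed=fo_seed, n_patients=n_patients)
        res = compare_arms(a, b)
        scatter.append((res.delta_cost, res.delta_qaly))
        dq_sum += res.delta_qaly
        dcost_sum += res.delta_cost
        dly_sum += res.delta_life_years
    dq, dcost = dq_sum / n_iterations, dcost_sum / n_iterations
    icer, dominance = _classify(dcost, dq)
    return CEResult(
        intervention=setup.intervention.arm_name,
        comparator=setup.comparator.arm_name,
        delta_qaly=dq,
        delta_cost=dcost,
        delta_life_years=dly_sum / n_iterations,
        icer=icer,
        dominance=dominance,
        scatter=scatter,
        ceac=ceac_from_scatter(scatter, wtp_grid),
    )


def outcomes_frame(outcomes: Sequence[ArmOutcome]) -> pd.DataFrame:
    return pd.DataFrame([o.summary_row() for o in outcomes])
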