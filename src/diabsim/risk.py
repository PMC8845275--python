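"""Annual complication and mortality risks.

Three parameterized mechanisms drive events each annual cycle:

* **Risk equations** (:class:`RiskCoefficientSet`) for first-ever / recurrent
  macrovascular and terminal events — Weibull proportional hazards on the
  diabetes-duration time scale, logistic, or constant-rate forms.  Which
  coefficient catalog is active (base case vs alternative set) is purely a
  data swap; the evaluation code path is identical.
* **Stage-chain transition tables** (:class:`TransitionTable`) for the
  microvascular complications (retinopathy, nephropathy, neuropathy, foot
  ulcers, macular edema, cataract), forward-only, optionally modified by
  HbA1c and by gating patient flags.
* **Poisson hypoglycemia counts** at the arm's annual rates, split into
  nocturnal/daytime by a binomial draw.

Mortality combines life-table background risk, acute case fatality for the
cycle's events, and chronic post-event excess risk as independent competing
risks.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Optional, Sequence

import yaml
from importlib import resources
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .config import (
    ConfigurationError,
    FOOT_STAGES,
    LifeTable,
    NEPHROPATHY_STAGES,
    PatientState,
    RETINOPATHY_STAGES,
)


class RiskCoefficientSet(BaseModel):
    """One parameterized risk equation.

    The linear predictor is ``L = intercept + sum_j coef_j * (x_j - center_j)``
    over covariate tags resolved against the patient state (see
    :func:`covariate_value`).  Forms:

    ``weibull_ph``
        cumulative hazard ``H(t) = exp(L) * t**shape`` with ``t`` = diabetes
        duration (years); the annual probability is
        ``1 - exp(H(t) - H(t+1))``.
    ``logistic``
        ``expit(L)``.
    ``constant_rate``
        annual probability ``1 - exp(-exp(L))`` (a Weibull with shape 1 at
        any duration).
    """

    model_config = ConfigDict(extra="forbid")

    outcome: str
    form: Literal["weibull_ph", "logistic", "constant_rate"]
    shape: float = Field(1.0, gt=0.0)
    intercept: float
    coefficients: dict[str, float] = {}
    covariate_centering: dict[str, float] = {}
    source_label: str = ""


def covariate_value(patient: PatientState, tag: str) -> float:
    """Resolve a covariate tag to its value for this patient.

    Derived covariates: ``age_diag`` (age at diagnosis), ``sbp10`` (SBP/10),
    ``lipid_ratio`` (TC/HDL), ``male``/``female``/``smoker`` indicators,
    ``active_ulcer``/``neuropathy_flag`` complication indicators.
    """
    if tag == "age":
        return patient.age
    if tag == "duration":
        return patient.duration
    if tag == "age_diag":
        return patient.age - patient.duration
    if tag == "hba1c":
        return patient.hba1c
    if tag == "sbp":
        return patient.sbp
    if tag == "sbp10":
        return patient.sbp / 10.0
    if tag == "tc":
        return patient.tc
    if tag == "hdl":
        return patient.hdl
    if tag == "lipid_ratio":
        return patient.tc / patient.hdl
    if tag == "bmi":
        return patient.bmi
    if tag == "egfr":
        return patient.egfr
    if tag == "male":
        return 1.0 if patient.sex == "male" else 0.0
    if tag == "female":
        return 1.0 if patient.sex == "female" else 0.0
    if tag == "smoker":
        return 1.0 if patient.smoker else 0.0
    if tag == "active_ulcer":
        return 1.0 if patient.foot_stage == "active_ulcer" else 0.0
    if tag == "neuropathy_flag":
        return 1.0 if patient.neuropathy else 0.0
    if tag == "mi_history":
        return 1.0 if patient.mi_history else 0.0
    if tag == "stroke_history":
        return 1.0 if patient.stroke_history else 0.0
    raise ConfigurationError(f"unknown covariate tag {tag!r}")


def linear_predictor(eq: RiskCoefficientSet, patient: PatientState) -> float:
    L = eq.intercept
    for tag, coef in eq.coefficients.items():
        center = eq.covariate_centering.get(tag, 0.0)
        L += coef * (covariate_value(patient, tag) - center)
    return L


def annual_event_probability(eq: RiskCoefficientSet, patient: PatientState) -> float:
    """Probability the equation's outcome occurs during the coming annual cycle."""
    L = linear_predictor(eq, patient)
    if eq.form == "logistic":
        return float(expit(L))
    if eq.form == "constant_rate":
        return 1.0 - math.exp(-math.exp(L))
    t = max(0.0, patient.duration)
    scale = math.exp(L)
    increment = scale * ((t + 1.0) ** eq.shape - t**eq.shape)
    return min(1.0, max(0.0, 1.0 - math.exp(-increment)))


def annual_death_probability(
    patient: PatientState,
    life_table: LifeTable,
    mortality_eqs: Iterable[RiskCoefficientSet],
    events_this_cycle: Sequence[str],
    active_states: Optional[Sequence[str]] = None,
) -> float:
    """Combined annual death probability from all sources.

    Background mortality (life-table lookup by age and sex), acute case
    fatality for each event of this cycle (``fatality:<event>`` equations)
    and chronic excess mortality for each active state (``excess:<state>``
    equations) are treated as independent competing risks:
    ``q = 1 - prod(1 - q_i)``, capped at 1.
    """
    from .config import active_state_tags  # local import to avoid cycle at module load

    q_background = life_table.annual_probability(patient.age, patient.sex)
    states = list(active_states) if active_states is not None else active_state_tags(patient)
    survive = 1.0 - q_background
    for eq in mortality_eqs:
        kind, _, tag = eq.outcome.partition(":")
        applies = (kind == "fatality" and tag in events_this_cycle) or (
            kind == "excess" and tag in states
        )
        if applies:
            survive *= 1.0 - annual_event_probability(eq, patient)
    return min(1.0, max(0.0, 1.0 - survive))


# --------------------------------------------------------------------------
# stage-chain transitions
# --------------------------------------------------------------------------


class TransitionGate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    flag: str
    multiplier: float = Field(ge=0.0)


class ChainTransition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    frm: str
    to: str
    probability: float = Field(ge=0.0, le=1.0)
    hba1c_rr_per_point: float = Field(1.0, gt=0.0)
    gates: list[TransitionGate] = []


class TransitionTable(BaseModel):
    """Forward-only annual transitions along one ordered complication chain."""

    model_config = ConfigDict(extra="forbid")

    name: str
    states: list[str]
    transitions: list[ChainTransition]

    @model_validator(mode="after")
    def _forward_only(self) -> "TransitionTable":
        index = {s: i for i, s in enumerate(self.states)}
        for tr in self.transitions:
            if tr.frm not in index or tr.to not in index:
                raise ValueError(f"chain {self.name}: unknown state in {tr.frm}->{tr.to}")
            if index[tr.to] <= index[tr.frm]:
                raise ValueError(f"chain {self.name}: backward transition {tr.frm}->{tr.to}")
        return self

    def effective_probability(self, tr: ChainTransition, patient: PatientState) -> float:
        p = tr.probability * tr.hba1c_rr_per_point ** (patient.hba1c - 7.0)
        for gate in tr.gates:
            if _gate_flag(patient, gate.flag):
                p *= gate.multiplier
        return min(1.0, max(0.0, p))

    def advance(self, current: str, patient: PatientState, u: float) -> str:
        """Advance the chain one cycle given uniform draw ``u``; at most one step."""
        cum = 0.0
        for tr in self.transitions:
            if tr.frm != current:
                continue
            cum += self.effective_probability(tr, patient)
            if u < cum:
                return tr.to
        return current


def _gate_flag(patient: PatientState, flag: str) -> bool:
    if flag == "any_retinopathy":
        return patient.retinopathy_stage != "none"
    if flag == "neuropathy":
        return patient.neuropathy
    if flag == "chf":
        return patient.chf
    if flag == "pvd":
        return patient.pvd
    raise ConfigurationError(f"unknown gate flag {flag!r}")


# --------------------------------------------------------------------------
# per-cycle event sampling
# --------------------------------------------------------------------------

#: fixed within-cycle order of the first-ever / recurrent event draws
EVENT_DRAW_ORDER = (
    "mi_event",
    "stroke_event",
    "chf_event",
    "angina_event",
    "pvd_event",
    "renal_failure_event",
    "amputation_event",
)

_NEPH_INDEX = {s: i for i, s in enumerate(NEPHROPATHY_STAGES)}
_FOOT_INDEX = {s: i for i, s in enumerate(FOOT_STAGES)}


def _equation_applies(tag: str, patient: PatientState) -> bool:
    # MI and stroke may recur in later cycles; the other events are first-ever.
    if tag == "chf_event":
        return not patient.chf
    if tag == "angina_event":
        return not patient.angina
    if tag == "pvd_event":
        return not patient.pvd
    if tag == "renal_failure_event":
        return _NEPH_INDEX[patient.nephropathy_stage] < _NEPH_INDEX["esrd_hemodialysis"]
    if tag == "amputation_event":
        return patient.foot_stage != "amputated"
    return True


def _apply_event(tag: str, patient: PatientState) -> None:
    if tag == "mi_event":
        patient.mi_history = True
    elif tag == "stroke_event":
        patient.stroke_history = True
    elif tag == "chf_event":
        patient.chf = True
    elif tag == "angina_event":
        patient.angina = True
    elif tag == "pvd_event":
        patient.pvd = True
    elif tag == "renal_failure_event":
        patient.nephropathy_stage = "esrd_hemodialysis"
    elif tag == "amputation_event":
        patient.foot_stage = "amputated"


def sample_cycle_events(
    patient: PatientState,
    equations: dict[str, RiskCoefficientSet],
    transitions: Sequence[TransitionTable],
    rng,
    nonsevere_hypo_rate: float = 0.0,
    severe_hypo_rate: float = 0.0,
    nocturnal_fraction_nonsevere: float = 0.0,
    nocturnal_fraction_severe: float = 0.0,
) -> PatientState:
    """Draw one annual cycle's events and mutate the patient state in place.

    Draw order is fixed for reproducibility: the acute-event equations in
    :data:`EVENT_DRAW_ORDER`, then each stage chain (catalog order), then
    hypoglycemia counts.  At most one occurrence per acute event type per
    cycle; chain stages advance at most one catalog transition per cycle.
    Hypoglycemia rates are per patient-year.
    """
    if not patient.alive:
        raise ValueError("cannot sample events for a dead patient")
    patient.reset_cycle()

    for tag in EVENT_DRAW_ORDER:
        eq = equations.get(tag)
        if eq is None or not _equation_applies(tag, patient):
            continue
        if rng.random() < annual_event_probability(eq, patient):
            patient.events_this_cycle.append(tag)
            _apply_event(tag, patient)

    for table in transitions:
        current = _chain_state(patient, table.name)
        if current is None:
            continue
        new = table.advance(current, patient, rng.random())
        if new != current:
            _set_chain_state(patient, table.name, new)
            tag = _chain_event_tag(table.name, new)
            if tag is not None:
                patient.events_this_cycle.append(tag)

    if nonsevere_hypo_rate > 0.0:
        n = int(rng.poisson(nonsevere_hypo_rate))
        noct = int(rng.binomial(n, nocturnal_fraction_nonsevere)) if n else 0
        patient.hypo_ns_noct = noct
        patient.hypo_ns_day = n - noct
    if severe_hypo_rate > 0.0:
        n = int(rng.poisson(severe_hypo_rate))
        noct = int(rng.binomial(n, nocturnal_fraction_severe)) if n else 0
        patient.hypo_sev_noct = noct
        patient.hypo_sev_day = n - noct
        patient.cum_severe_hypo += n
    return patient


def _chain_state(patient: PatientState, chain: str) -> Optional[str]:
    """Current stage of a named chain, or None when the chain cannot advance."""
    if chain == "retinopathy":
        return patient.retinopathy_stage
    if chain == "nephropathy":
        return patient.nephropathy_stage
    if chain == "neuropathy":
        return "neuropathy" if patient.neuropathy else "none"
    if chain == "foot_ulcer":
        return None if patient.foot_stage == "amputated" else patient.foot_stage
    if chain == "macular_edema":
        return "macular_edema" if patient.macular_edema else "none"
    if chain == "cataract":
        return "cataract" if patient.cataract else "none"
    raise ConfigurationError(f"unknown transition chain {chain!r}")


def _set_chain_state(patient: PatientState, chain: str, stage: str) -> None:
    if chain == "retinopathy":
        patient.retinopathy_stage = stage
    elif chain == "nephropathy":
        patient.nephropathy_stage = stage
    elif chain == "neuropathy":
        patient.neuropathy = stage == "neuropathy"
    elif chain == "foot_ulcer":
        patient.foot_stage = stage
    elif chain == "macular_edema":
        patient.macular_edema = stage == "macular_edema"
    elif chain == "cataract":
        patient.cataract = stage == "cataract"


def _chain_event_tag(chain: str, stage: str) -> Optional[str]:
    """Acute event tag for a chain advance, or None for a silent stage change.

    Plain stage progressions (retinopathy, nephropathy, neuropathy) carry no
    acute event cost/disutility; their burden accrues through the new
    state's annual utility decrement and cost from the next cycle.
    """
    if chain == "foot_ulcer" and stage == "active_ulcer":
        return "ulcer_event"
    if chain == "macular_edema":
        return "macular_edema_event"
    if chain == "cataract":
        return "cataract_event"
    return None


def simulate_hypoglycemia_rates(
    nonsevere_rate: float,
    severe_rate: float,
    patient_years: int,
    seed: int,
) -> tuple[float, float]:
    """Empirical mean (non-severe, severe) event rates over simulated patient-years.

    Runs the engine's per-cycle hypoglycemia sampling on a basal-insulin
    patient with all complication risks disabled, one cycle per patient-year.
    """
    import numpy as np

    patient = PatientState(
        age=60.0, sex="male", duration=10.0, hba1c=7.5, sbp=130.0, tc=180.0,
        hdl=45.0, bmi=30.0, egfr=90.0, smoker=False, baseline_bmi=30.0,
        therapy="basal_insulin",
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ns_total = sev_total = 0
    for _ in range(patient_years):
        sample_cycle_events(
            patient, {}, [], rng,
            nonsevere_hypo_rate=nonsevere_rate, severe_hypo_rate=severe_rate,
        )
        ns_total += patient.hypo_ns_day + patient.hypo_ns_noct
        sev_total += patient.hypo_sev_day + patient.hypo_sev_noct
    return ns_total / patient_years, sev_total / patient_years


# --------------------------------------------------------------------------
# packaged catalogs
# --------------------------------------------------------------------------


def _read_packaged(name: str) -> dict:
    text = (resources.files("diabsim") / "data" / name).read_text()
    return yaml.safe_load(text)


def load_risk_set(name: str = "ukpds68") -> dict[str, RiskCoefficientSet]:
    """Load a packaged risk-equation catalog keyed by outcome tag."""
    if name not in ("ukpds68", "ukpds82"):
        raise ConfigurationError(f"unknown risk set {name!r}")
    data = _read_packaged(f"risk_{name}.yaml")
    eqs = [RiskCoefficientSet.model_validate(e) for e in data["equations"]]
    return {eq.outcome: eq for eq in eqs}


def load_mortality_model() -> list[RiskCoefficientSet]:
    data = _read_packaged("mortality.yaml")
    return [RiskCoefficientSet.model_validate(e) for e in data["equations"]]


def load_transition_tables() -> list[TransitionTable]:
    data = _read_packaged("transitions.yaml")
    return [TransitionTable.model_validate(c) for c in data["chains"]]
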