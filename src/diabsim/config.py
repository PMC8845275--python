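"""Typed parameter catalogs, study configuration and the simulated patient state.

Every quantitative input of the analysis lives in a validated catalog object
(:class:`CohortSpec`, :class:`TreatmentEffectProfile`, :class:`UtilityCatalog`
friends in :mod:`diabsim.economics`, risk-equation sets in
:mod:`diabsim.risk`) that is loaded from packaged YAML files and can be
round-tripped to user-editable files.  The catalogs hold the published trial
baselines and first-year treatment effects for the two head-to-head
comparisons modelled here:

* ``pioneer2`` — oral semaglutide 14 mg vs empagliflozin 25 mg, baseline
  cohort and effects from a 52-week randomized trial (trial-product
  estimand);
* ``nma`` — oral semaglutide 14 mg vs dulaglutide 1.5 mg, baseline cohort
  from a second trial in the same programme and effects from a network
  meta-analysis (unmodelled parameters set to zero).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class ConfigurationError(RuntimeError):
    """A catalog is missing an entry (covariate, tag, therapy key) the engine needs."""


# --------------------------------------------------------------------------
# canonical tag sets
# --------------------------------------------------------------------------

#: chronic health states that carry an annual utility (and possibly a cost)
STATE_TAGS = (
    "post_mi",
    "angina",
    "chf",
    "post_stroke",
    "pvd",
    "microalbuminuria",
    "gross_proteinuria",
    "hemodialysis",
    "peritoneal_dialysis",
    "renal_transplant",
    "bdr",
    "pdr",
    "macular_edema",
    "svl",
    "cataract",
    "neuropathy",
    "healed_ulcer",
    "active_ulcer",
    "post_amputation",
)

#: acute event tags the engine can emit during a cycle
EVENT_TAGS = (
    "mi_event",
    "stroke_event",
    "chf_event",
    "angina_event",
    "pvd_event",
    "renal_failure_event",
    "amputation_event",
    "ulcer_event",
    "macular_edema_event",
    "cataract_event",
)

NEPHROPATHY_STAGES = (
    "none",
    "microalbuminuria",
    "gross_proteinuria",
    "esrd_hemodialysis",
    "esrd_peritoneal",
    "esrd_transplant",
)
RETINOPATHY_STAGES = ("none", "bdr", "pdr", "svl")
FOOT_STAGES = ("none", "active_ulcer", "healed_ulcer", "amputated")


# --------------------------------------------------------------------------
# cohort and treatment-effect catalogs
# --------------------------------------------------------------------------


class Dist(BaseModel):
    """A (mean, sd) pair describing a baseline characteristic's distribution."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd: float = Field(0.0, ge=0.0)


class CohortSpec(BaseModel):
    """Baseline cohort characteristics of one trial population.

    Continuous characteristics are (mean, sd) pairs; ``proportion_male`` and
    ``proportion_smoker`` are Bernoulli fractions.  Units: age and duration in
    years, HbA1c in %, SBP in mmHg, BMI in kg/m^2, lipids in mg/dL, eGFR in
    mL/min/1.73m^2, alcohol in oz/week.
    """

    model_config = ConfigDict(extra="forbid")

    label: str
    start_age: Dist
    diabetes_duration: Dist
    proportion_male: float = Field(ge=0.0, le=1.0)
    hba1c: Dist
    sbp: Dist
    bmi: Dist
    total_cholesterol: Dist
    hdl: Dist
    egfr: Dist
    proportion_smoker: float = Field(ge=0.0, le=1.0)
    cigarettes_per_day: int = Field(ge=0)
    alcohol_oz_per_week: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _positive_means(self) -> "CohortSpec":
        for name in ("start_age", "hba1c", "bmi"):
            if getattr(self, name).mean <= 0:
                raise ValueError(f"{name}.mean must be strictly positive")
        return self


class EffectSize(BaseModel):
    """A first-year treatment effect: mean change from baseline with its SE."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    se: float = Field(0.0, ge=0.0)
    #: statistically significant difference vs the comparator at the 95% level
    significant: bool = True


class TreatmentEffectProfile(BaseModel):
    """First-year physiological effects and on-therapy adverse-event rates of one arm.

    Hypoglycemia rates are expressed per 100 patient-years, as published;
    the engine divides by 100.  They apply while the patient remains on the
    initial therapy; post-intensification rates come from
    :class:`SimulationConfig`.
    """

    model_config = ConfigDict(extra="forbid")

    arm_name: str
    delta_hba1c: EffectSize
    delta_sbp: EffectSize
    delta_tc: EffectSize
    delta_hdl: EffectSize
    delta_bmi: EffectSize
    delta_egfr: EffectSize
    nonsevere_hypo_rate: float = Field(ge=0.0, description="events per 100 patient-years")
    severe_hypo_rate: float = Field(ge=0.0, description="events per 100 patient-years")
    nocturnal_fraction_nonsevere: float = Field(ge=0.0, le=1.0)
    nocturnal_fraction_severe: float = Field(ge=0.0, le=1.0)
    annual_therapy_cost_key: str


# --------------------------------------------------------------------------
# progression laws and intensification policies
# --------------------------------------------------------------------------


class ProgressionLaw(BaseModel):
    """Annual HbA1c update rule.

    ``ukpds_ar`` is a first-order autoregression toward a duration-dependent
    attractor::

        h' = w * h + (1 - w) * (a + b * duration)

    which increases HbA1c whenever the current value lies below the attractor
    ``a + b * duration`` and contracts between-arm differences geometrically
    (factor ``w`` per year).  ``linear`` adds a constant slope each year.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["ukpds_ar", "linear"] = "ukpds_ar"
    ar_weight: float = Field(0.72, gt=0.0, le=1.0)
    attractor_intercept: float = 7.8
    attractor_slope: float = 0.05
    linear_slope: float = 0.15

    @model_validator(mode="after")
    def _finite(self) -> "ProgressionLaw":
        for v in (self.attractor_intercept, self.attractor_slope, self.linear_slope):
            if not math.isfinite(v):
                raise ValueError("progression-law parameters must be finite")
        return self


class IntensificationPolicy(BaseModel):
    """HbA1c response applied when the patient intensifies to basal insulin.

    ``willis_linear`` applies a reduction ``max(0, intercept + slope * h)``
    (a multivariate-regression-style response for an insulin-naive
    population, coefficients user-editable); ``target_value`` sets HbA1c to a
    fixed post-switch value; ``none`` leaves HbA1c unchanged.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["willis_linear", "target_value", "none"] = "willis_linear"
    willis_intercept: float = -2.55
    willis_slope: float = 0.45
    target_hba1c: float = Field(7.0, gt=0.0)

    def reduction(self, hba1c: float) -> float:
        """Signed HbA1c drop (>= 0) applied on intensification."""
        if self.kind == "none":
            return 0.0
        if self.kind == "target_value":
            return max(0.0, hba1c - self.target_hba1c)
        return max(0.0, self.willis_intercept + self.willis_slope * hba1c)


class FactorDrift(BaseModel):
    """AR(1) drift of a secondary risk factor toward a fixed attractor."""

    model_config = ConfigDict(extra="forbid")

    ar_weight: float = Field(1.0, gt=0.0, le=1.0)
    attractor: float = 0.0


class SecondaryDrift(BaseModel):
    """Natural-progression drifts for SBP and serum lipids."""

    model_config = ConfigDict(extra="forbid")

    sbp: FactorDrift = FactorDrift(ar_weight=0.97, attractor=145.0)
    tc: FactorDrift = FactorDrift(ar_weight=0.98, attractor=195.0)
    hdl: FactorDrift = FactorDrift(ar_weight=1.0, attractor=45.0)


class SimulationConfig(BaseModel):
    """Run-level settings: horizon, discounting, switching rule, model variants."""

    model_config = ConfigDict(extra="forbid")

    horizon_years: int = Field(50, ge=1)
    discount_rate_costs: float = Field(0.04, ge=0.0)
    discount_rate_effects: float = Field(0.04, ge=0.0)
    n_patients: int = Field(10_000, ge=1)
    seed: int = 12345
    switch_threshold_hba1c: float = Field(7.5, gt=0.0)
    #: when set, patients switch after this many years regardless of HbA1c
    switch_fixed_year: Optional[int] = Field(None, ge=1)
    intensification_policy: IntensificationPolicy = IntensificationPolicy()
    hba1c_law: ProgressionLaw = ProgressionLaw()
    secondary_drift: SecondaryDrift = SecondaryDrift()
    bmi_persistence: Literal["revert_on_switch", "maintain_lifetime"] = "revert_on_switch"
    risk_set: Literal["ukpds68", "ukpds82"] = "ukpds68"
    #: hypoglycemia rates after intensification, events per patient-year
    basal_nonsevere_hypo_rate: float = Field(4.08, ge=0.0)
    basal_severe_hypo_rate: float = Field(0.10, ge=0.0)
    utility_model_bmi: Literal["beaudet", "lee"] = "beaudet"
    hypo_disutility_model: Literal["evans", "currie", "lauridsen_diminishing"] = "evans"
    death_accrual: Literal["half_cycle", "full_cycle"] = "half_cycle"
    #: multiplies every complication event/state cost (sensitivity lever)
    complication_cost_multiplier: float = Field(1.0, ge=0.0)


# --------------------------------------------------------------------------
# life table
# --------------------------------------------------------------------------


class LifeTableRow(BaseModel):
    model_config = ConfigDict(extra="forbid")

    age_lo: float
    age_hi: float
    sex: Literal["male", "female"]
    q: float = Field(ge=0.0, le=1.0, description="annual mortality probability")


class LifeTable(BaseModel):
    """Age- and sex-banded annual background mortality probabilities.

    Bands must be contiguous and non-overlapping per sex; any age at or
    beyond the end of the last band maps to probability 1.  Ages below the
    first band are a configuration error.
    """

    model_config = ConfigDict(extra="forbid")

    rows: list[LifeTableRow]

    @model_validator(mode="after")
    def _contiguous(self) -> "LifeTable":
        for sex in ("male", "female"):
            bands = sorted(
                (r for r in self.rows if r.sex == sex), key=lambda r: r.age_lo
            )
            if not bands:
                raise ValueError(f"life table has no rows for sex={sex}")
            for a, b in zip(bands, bands[1:]):
                if not math.isclose(a.age_hi, b.age_lo):
                    raise ValueError(
                        f"life-table bands for {sex} are not contiguous at age {a.age_hi}"
                    )
        return self

    def _bands(self, sex: str) -> list[LifeTableRow]:
        return sorted((r for r in self.rows if r.sex == sex), key=lambda r: r.age_lo)

    def annual_probability(self, age: float, sex: str) -> float:
        bands = self._bands(sex)
        if age < bands[0].age_lo:
            raise ConfigurationError(
                f"age {age} below life-table start {bands[0].age_lo}"
            )
        if age >= bands[-1].age_hi:
            return 1.0
        for row in bands:
            if row.age_lo <= age < row.age_hi:
                return row.q
        raise ConfigurationError(f"no life-table band covers age {age}")  # pragma: no cover


# --------------------------------------------------------------------------
# patient state
# --------------------------------------------------------------------------


@dataclass(slots=True)
class PatientState:
    """One simulated individual: risk factors, complication history, therapy status.

    Stage fields only move forward along their ordered chains; a dead patient
    (``alive=False``) never accrues further events.  ``events_this_cycle`` and
    the four hypoglycemia counts describe the current annual cycle only and
    are reset each cycle by the engine.
    """

    age: float
    sex: str  # 'male' | 'female'
    duration: float
    hba1c: float
    sbp: float
    tc: float
    hdl: float
    bmi: float
    egfr: float
    smoker: bool
    baseline_bmi: float
    mi_history: bool = False
    angina: bool = False
    chf: bool = False
    stroke_history: bool = False
    pvd: bool = False
    nephropathy_stage: str = "none"
    retinopathy_stage: str = "none"
    macular_edema: bool = False
    cataract: bool = False
    neuropathy: bool = False
    foot_stage: str = "none"
    therapy: str = "initial"  # 'initial' | 'basal_insulin'
    years_on_therapy: float = 0.0
    years_on_initial: float = 0.0
    alive: bool = True
    events_this_cycle: list = field(default_factory=list)
    hypo_ns_day: int = 0
    hypo_ns_noct: int = 0
    hypo_sev_day: int = 0
    hypo_sev_noct: int = 0
    cum_severe_hypo: int = 0

    def validate(self) -> None:
        """Raise ValueError on physically impossible field values."""
        if self.hba1c <= 0 or self.bmi <= 0:
            raise ValueError("hba1c and bmi must be strictly positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.nephropathy_stage not in NEPHROPATHY_STAGES:
            raise ValueError(f"unknown nephropathy stage {self.nephropathy_stage!r}")
        if self.retinopathy_stage not in RETINOPATHY_STAGES:
            raise ValueError(f"unknown retinopathy stage {self.retinopathy_stage!r}")
        if self.foot_stage not in FOOT_STAGES:
            raise ValueError(f"unknown foot stage {self.foot_stage!r}")
        if self.therapy not in ("initial", "basal_insulin"):
            raise ValueError(f"unknown therapy {self.therapy!r}")

    def reset_cycle(self) -> None:
        self.events_this_cycle = []
        self.hypo_ns_day = self.hypo_ns_noct = 0
        self.hypo_sev_day = self.hypo_sev_noct = 0


def active_state_tags(patient: PatientState) -> list[str]:
    """Chronic health-state tags currently active for utility/cost accrual.

    Each staged chain contributes its current stage only (a patient with
    gross proteinuria does not also carry the microalbuminuria decrement).
    """
    tags: list[str] = []
    if patient.mi_history:
        tags.append("post_mi")
    if patient.angina:
        tags.append("angina")
    if patient.chf:
        tags.append("chf")
    if patient.stroke_history:
        tags.append("post_stroke")
    if patient.pvd:
        tags.append("pvd")
    neph = {
        "microalbuminuria": "microalbuminuria",
        "gross_proteinuria": "gross_proteinuria",
        "esrd_hemodialysis": "hemodialysis",
        "esrd_peritoneal": "peritoneal_dialysis",
        "esrd_transplant": "renal_transplant",
    }.get(patient.nephropathy_stage)
    if neph:
        tags.append(neph)
    if patient.retinopathy_stage != "none":
        tags.append(patient.retinopathy_stage)
    if patient.macular_edema:
        tags.append("macular_edema")
    if patient.cataract:
        tags.append("cataract")
    if patient.neuropathy:
        tags.append("neuropathy")
    foot = {
        "active_ulcer": "active_ulcer",
        "healed_ulcer": "healed_ulcer",
        "amputated": "post_amputation",
    }.get(patient.foot_stage)
    if foot:
        tags.append(foot)
    return tags


# --------------------------------------------------------------------------
# packaged parameter files
# --------------------------------------------------------------------------


def _read_packaged(name: str) -> dict:
    text = (resources.files("diabsim") / "data" / name).read_text()
    return yaml.safe_load(text)


def load_cohort_spec(name: str) -> CohortSpec:
    """Load a packaged baseline cohort (``pioneer2`` or ``pioneer3``)."""
    data = _read_packaged("cohorts.yaml")
    if name not in data:
        raise ConfigurationError(f"unknown cohort {name!r}; have {sorted(data)}")
    return CohortSpec.model_validate(data[name])


def load_effect_profiles(comparison: str) -> tuple[TreatmentEffectProfile, TreatmentEffectProfile]:
    """Load the (intervention, comparator) effect profiles of a comparison."""
    data = _read_packaged("effects.yaml")
    if comparison not in data:
        raise ConfigurationError(f"unknown comparison {comparison!r}; have {sorted(data)}")
    block = data[comparison]
    return (
        TreatmentEffectProfile.model_validate(block["intervention"]),
        TreatmentEffectProfile.model_validate(block["comparator"]),
    )


def load_base_config() -> SimulationConfig:
    return SimulationConfig.model_validate(_read_packaged("simulation.yaml"))


def load_life_table() -> LifeTable:
    return LifeTable.model_validate(_read_packaged("life_table_synthetic.yaml"))


def load_study_config(
    comparison: str,
) -> tuple[CohortSpec, tuple[TreatmentEffectProfile, TreatmentEffectProfile], SimulationConfig]:
    """Return (cohort spec, (intervention, comparator) profiles, base-case config).

    ``comparison`` is ``'pioneer2'`` (oral semaglutide vs empagliflozin,
    trial baseline cohort) or ``'nma'`` (oral semaglutide vs dulaglutide,
    companion-trial baseline cohort, meta-analysis effects).
    """
    if comparison not in ("pioneer2", "nma"):
        raise ConfigurationError(
            f"comparison must be 'pioneer2' or 'nma', got {comparison!r}"
        )
    cohort = load_cohort_spec("pioneer2" if comparison == "pioneer2" else "pioneer3")
    profiles = load_effect_profiles(comparison)
    return cohort, profiles, load_base_config()


def dump_model_yaml(model: BaseModel) -> str:
    """Serialize any catalog/config model to YAML (round-trips via its loader)."""
    return yaml.safe_dump(model.model_dump(mode="json"), sort_keys=False)
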