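"""QALY and cost accrual with discounting.

Annual utility is built additively: the complication-free baseline utility,
minus one decrement per active chronic state (decrement = baseline minus the
state's published utility, so a patient whose only state is post-amputation
scores exactly the published post-amputation utility), minus event
disutilities for this cycle's acute events, minus per-event hypoglycemia
decrements, minus a per-unit decrement for BMI above the reference
(25 kg/m^2), floored at zero.  Costs accrue per cycle into the lifetime
cost categories (treatment, management, hypoglycemia, cardiovascular,
renal, ophthalmic, neuropathy/foot).  Present values use annual discounting
with the first cycle undiscounted (exponent 0).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import ConfigurationError, PatientState, STATE_TAGS, active_state_tags
from .treatment import CostCatalog

#: lifetime direct-cost categories
COST_CATEGORIES = (
    "treatment",
    "management",
    "hypoglycemia",
    "cardiovascular",
    "renal",
    "ophthalmic",
    "neuropathy_foot",
)

_TAG_CATEGORY = {
    "mi_event": "cardiovascular",
    "stroke_event": "cardiovascular",
    "chf_event": "cardiovascular",
    "angina_event": "cardiovascular",
    "pvd_event": "cardiovascular",
    "post_mi": "cardiovascular",
    "post_stroke": "cardiovascular",
    "angina": "cardiovascular",
    "chf": "cardiovascular",
    "pvd": "cardiovascular",
    "renal_failure_event": "renal",
    "microalbuminuria": "renal",
    "gross_proteinuria": "renal",
    "hemodialysis": "renal",
    "peritoneal_dialysis": "renal",
    "renal_transplant": "renal",
    "macular_edema_event": "ophthalmic",
    "cataract_event": "ophthalmic",
    "bdr": "ophthalmic",
    "pdr": "ophthalmic",
    "svl": "ophthalmic",
    "macular_edema": "ophthalmic",
    "cataract": "ophthalmic",
    "amputation_event": "neuropathy_foot",
    "ulcer_event": "neuropathy_foot",
    "neuropathy": "neuropathy_foot",
    "active_ulcer": "neuropathy_foot",
    "healed_ulcer": "neuropathy_foot",
    "post_amputation": "neuropathy_foot",
}


class UtilityCatalog(BaseModel):
    """State utilities, event disutilities and the BMI decrement.

    State utilities are in [0, 1]; event, hypoglycemia and BMI decrements
    are signed (<= 0).  Alternative-model entries (``lee_*``, ``currie_*``,
    ``lauridsen_rho``) hold the parameters of the sensitivity-analysis
    disutility models and are selected at evaluation time.
    """

    model_config = ConfigDict(extra="forbid")

    baseline_utility: float = Field(ge=0.0, le=1.0)
    state_utilities: dict[str, float]
    event_disutilities: dict[str, float]
    hypo_disutilities: dict[str, float]
    currie_hypo_disutilities: dict[str, float] = {}
    lauridsen_rho: float = Field(0.8, gt=0.0, le=1.0)
    bmi_disutility_per_unit: float = Field(le=0.0)
    lee_bmi_disutility_per_unit: float = Field(-0.0038, le=0.0)
    bmi_reference: float = Field(25.0, gt=0.0)

    @model_validator(mode="after")
    def _complete_and_signed(self) -> "UtilityCatalog":
        missing = [t for t in STATE_TAGS if t not in self.state_utilities]
        if missing:
            raise ValueError(f"state_utilities missing tags: {missing}")
        for tag, u in self.state_utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"state utility for {tag!r} outside [0, 1]")
        for d in (self.event_disutilities, self.hypo_disutilities, self.currie_hypo_disutilities):
            for tag, v in d.items():
                if v > 0:
                    raise ValueError(f"disutility for {tag!r} must be <= 0 (signed)")
        return self

    def state_decrement(self, tag: str) -> float:
        """Decrement (>= 0) for one active state: baseline minus state utility."""
        if tag not in self.state_utilities:
            raise ConfigurationError(f"unknown state tag {tag!r}")
        return self.baseline_utility - self.state_utilities[tag]


def _hypo_decrement(
    catalog: UtilityCatalog,
    patient: PatientState,
    model: str,
) -> float:
    """Total (positive) hypoglycemia decrement for this cycle's events."""
    if model == "currie":
        table = catalog.currie_hypo_disutilities or catalog.hypo_disutilities
    else:
        table = catalog.hypo_disutilities
    counts = {
        "nonsevere_daytime": patient.hypo_ns_day,
        "nonsevere_nocturnal": patient.hypo_ns_noct,
        "severe_daytime": patient.hypo_sev_day,
        "severe_nocturnal": patient.hypo_sev_noct,
    }
    if model != "lauridsen_diminishing":
        return sum(-table[k] * c for k, c in counts.items() if c)
    # Diminishing model: the k-th lifetime severe event carries rho^(k-1)
    # of the full severe decrement; non-severe events are undiminished.
    total = -table["nonsevere_daytime"] * counts["nonsevere_daytime"]
    total += -table["nonsevere_nocturnal"] * counts["nonsevere_nocturnal"]
    n_sev = counts["severe_daytime"] + counts["severe_nocturnal"]
    if n_sev:
        frac_noct = counts["severe_nocturnal"] / n_sev
        per_event = -(
            table["severe_nocturnal"] * frac_noct
            + table["severe_daytime"] * (1.0 - frac_noct)
        )
        first_index = patient.cum_severe_hypo - n_sev  # events before this cycle
        rho = catalog.lauridsen_rho
        total += per_event * sum(rho ** (first_index + k) for k in range(n_sev))
    return total


def state_utility_component(
    patient_or_tags,
    catalog: UtilityCatalog,
    bmi: Optional[float] = None,
    bmi_model: str = "beaudet",
) -> float:
    """Baseline utility minus state and BMI decrements (no events), unfloored.

    Accepts either a :class:`PatientState` or an iterable of state tags plus
    an explicit BMI (the engine evaluates on a start-of-cycle snapshot).
    """
    if isinstance(patient_or_tags, PatientState):
        tags = active_state_tags(patient_or_tags)
        bmi = patient_or_tags.bmi
    else:
        tags = list(patient_or_tags)
        if bmi is None:
            raise ValueError("bmi required when passing state tags")
    u = catalog.baseline_utility
    for tag in tags:
        u -= catalog.state_decrement(tag)
    per_unit = (
        catalog.lee_bmi_disutility_per_unit
        if bmi_model == "lee"
        else catalog.bmi_disutility_per_unit
    )
    u += per_unit * max(0.0, bmi - catalog.bmi_reference)
    return u


def annual_utility(
    patient: PatientState,
    catalog: UtilityCatalog,
    bmi_model: str = "beaudet",
    hypo_model: str = "evans",
) -> float:
    """Utility of one full patient-year in the current state, floored at 0.

    Event disutilities are looked up for this cycle's acute events (events
    with no published disutility contribute nothing); hypoglycemia
    decrements are applied per event under the selected model.
    """
    u = state_utility_component(patient, catalog, bmi_model=bmi_model)
    for tag in patient.events_this_cycle:
        u += catalog.event_disutilities.get(tag, 0.0)
    u -= _hypo_decrement(catalog, patient, hypo_model)
    return max(0.0, u)


def annual_cost(
    patient: PatientState,
    catalog: CostCatalog,
    therapy_cost: float,
    complication_cost_multiplier: float = 1.0,
    state_tags: Optional[Sequence[str]] = None,
    state_fraction: float = 1.0,
) -> dict[str, float]:
    """One cycle's direct costs broken down by lifetime cost category.

    ``state_fraction`` scales therapy, management and chronic-state costs
    (0.5 in a half-cycle death year); acute event costs always accrue in
    full.  Chronic states default to the patient's currently active states.
    """
    breakdown = {cat: 0.0 for cat in COST_CATEGORIES}
    breakdown["treatment"] = therapy_cost * state_fraction
    breakdown["management"] = catalog.management_annual_cost * state_fraction
    m = complication_cost_multiplier
    for tag in patient.events_this_cycle:
        if tag not in catalog.event_costs:
            raise ConfigurationError(f"no event cost entry for {tag!r}")
        breakdown[_TAG_CATEGORY[tag]] += catalog.event_costs[tag] * m
    n_ns = patient.hypo_ns_day + patient.hypo_ns_noct
    n_sev = patient.hypo_sev_day + patient.hypo_sev_noct
    if n_ns or n_sev:
        for key, count in (("hypo_nonsevere", n_ns), ("hypo_severe", n_sev)):
            if key not in catalog.event_costs:
                raise ConfigurationError(f"no event cost entry for {key!r}")
            breakdown["hypoglycemia"] += catalog.event_costs[key] * count * m
    tags = list(state_tags) if state_tags is not None else active_state_tags(patient)
    for tag in tags:
        if tag not in catalog.state_annual_costs:
            raise ConfigurationError(f"no state cost entry for {tag!r}")
        breakdown[_TAG_CATEGORY[tag]] += (
            catalog.state_annual_costs[tag] * m * state_fraction
        )
    return breakdown


def discount_stream(values: Iterable[float], rate: float) -> float:
    """Present value of an annual stream; the first cycle is undiscounted.

    ``PV = sum_t values[t] / (1 + rate)^t`` with ``t = 0`` for the first
    cycle.  A zero rate returns the arithmetic sum.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return 0.0
    weights = (1.0 + rate) ** -np.arange(arr.size)
    return float(arr @ weights)


class DiscountedLedger:
    """Per-cycle accumulator of utility, survival fraction and category costs."""

    def __init__(self, rate_costs: float, rate_effects: float) -> None:
        if rate_costs < 0 or rate_effects < 0:
            raise ValueError("discount rates must be >= 0")
        self.rate_costs = rate_costs
        self.rate_effects = rate_effects
        self.utility: list[float] = []
        self.life_fraction: list[float] = []
        self.costs: list[dict[str, float]] = []

    def record(self, utility: float, life_fraction: float, costs: dict[str, float]) -> None:
        self.utility.append(utility)
        self.life_fraction.append(life_fraction)
        self.costs.append(costs)

    @property
    def discounted_qalys(self) -> float:
        return discount_stream(self.utility, self.rate_effects)

    @property
    def discounted_life_years(self) -> float:
        return discount_stream(self.life_fraction, self.rate_effects)

    @property
    def undiscounted_life_years(self) -> float:
        return float(sum(self.life_fraction))

    def discounted_costs(self) -> dict[str, float]:
        out = {}
        for cat in COST_CATEGORIES:
            out[cat] = discount_stream((c[cat] for c in self.costs), self.rate_costs)
        out["total"] = sum(out.values())
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, (u, lf, c) in enumerate(zip(self.utility, self.life_fraction, self.costs), 1):
            rows.append({"cycle": t, "utility": u, "life_fraction": lf, **c})
        return pd.DataFrame(rows)


def load_utility_catalog() -> UtilityCatalog:
    text = (resources.files("diabsim") / "data" / "utilities.yaml").read_text()
    return UtilityCatalog.model_validate(yaml.safe_load(text))
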