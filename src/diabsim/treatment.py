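"""Treatment-pathway state machine and therapy acquisition costs.

Patients follow exactly one pathway: initial therapy (oral semaglutide,
empagliflozin or dulaglutide) until glycemic control is lost, then basal
insulin for the rest of the simulation.  The switch trigger is strict:
end-of-cycle HbA1c must *exceed* the threshold (7.5% in the base case);
the switch takes effect at the start of the next cycle and the basal-insulin
state is absorbing.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .config import ConfigurationError, PatientState

#: days per year used to annualize daily resource use
DAYS_PER_YEAR = 365.25

#: defined daily dose of basal insulin, IU/day (weight-independent)
BASAL_INSULIN_DAILY_IU = 40.0


class CostCatalog(BaseModel):
    """Unit costs of therapies, complication events, chronic state-years and management.

    ``comparator_price_multiplier`` scales only the comparator arm's therapy
    acquisition cost (a pricing sensitivity lever); all other entries apply
    to both arms.
    """

    model_config = ConfigDict(extra="forbid")

    currency_label: str
    therapy_daily_cost: dict[str, float]
    insulin_cost_per_iu: float = Field(ge=0.0)
    needle_cost: float = Field(ge=0.0, description="cost per needle")
    smbg_strip_cost: float = Field(ge=0.0, description="cost per glucose test strip")
    event_costs: dict[str, float]
    state_annual_costs: dict[str, float]
    management_annual_cost: float = Field(ge=0.0)
    comparator_price_multiplier: float = Field(1.0, ge=0.0)

    @field_validator("therapy_daily_cost", "event_costs", "state_annual_costs")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for key, cost in v.items():
            if cost < 0:
                raise ValueError(f"cost for {key!r} must be >= 0")
        return v


def evaluate_switch(patient: PatientState, threshold: float) -> bool:
    """True iff the patient intensifies to basal insulin after this cycle.

    Strict inequality at the threshold: HbA1c exactly at the threshold does
    not trigger a switch.  Patients already on basal insulin never switch
    again.
    """
    if not patient.alive:
        raise ValueError("cannot evaluate switching for a dead patient")
    return patient.therapy == "initial" and patient.hba1c > threshold


def annual_therapy_cost(
    patient: PatientState,
    catalog: CostCatalog,
    therapy_key: str,
    is_comparator: bool = False,
) -> float:
    """Annual acquisition cost of the patient's current therapy.

    On initial therapy: ``365.25 * daily drug cost`` — no needles or glucose
    strips (oral drugs, or needles bundled with the injectable pack).  On
    basal insulin: ``365.25 * (40 IU * cost/IU + 1 needle + 1 strip)``.
    The comparator arm's initial-therapy cost is multiplied by
    ``comparator_price_multiplier``.
    """
    if patient.therapy == "basal_insulin":
        daily = (
            BASAL_INSULIN_DAILY_IU * catalog.insulin_cost_per_iu
            + catalog.needle_cost
            + catalog.smbg_strip_cost
        )
        return DAYS_PER_YEAR * daily
    if therapy_key not in catalog.therapy_daily_cost:
        raise ConfigurationError(f"no therapy cost entry for {therapy_key!r}")
    cost = DAYS_PER_YEAR * catalog.therapy_daily_cost[therapy_key]
    if is_comparator:
        cost *= catalog.comparator_price_multiplier
    return cost
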