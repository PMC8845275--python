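"""Annual risk-factor progression and treatment-intensification response.

Cycle 1 applies the arm's published first-year effects to every risk
factor.  From cycle 2 onward HbA1c follows the configured progression law
(autoregression toward a duration-dependent attractor in the base case,
which recreates the published behaviour of HbA1c rising over time with
between-arm differences gradually shrinking), SBP and serum lipids drift
via the same AR form toward their own attractors, BMI is held at the
treated value while the patient stays on initial therapy, and eGFR is
carried unchanged.  On intensification the configured policy reduces HbA1c,
BMI reverts to baseline (unless treatment effects are configured to persist
for life), and hypoglycemia rates jump to the basal-insulin rates.
"""

from __future__ import annotations

from .config import (
    IntensificationPolicy,
    PatientState,
    ProgressionLaw,
    SecondaryDrift,
    TreatmentEffectProfile,
)


def apply_first_year_effects(
    patient: PatientState, profile: TreatmentEffectProfile
) -> PatientState:
    """Add the arm's first-year changes from baseline to each risk factor."""
    patient.hba1c += profile.delta_hba1c.mean
    patient.sbp += profile.delta_sbp.mean
    patient.tc += profile.delta_tc.mean
    patient.hdl += profile.delta_hdl.mean
    patient.bmi += profile.delta_bmi.mean
    patient.egfr += profile.delta_egfr.mean
    return patient


def progress_hba1c(patient: PatientState, law: ProgressionLaw) -> PatientState:
    """One annual HbA1c progression step (cycles >= 2); never goes negative."""
    if law.kind == "linear":
        new = patient.hba1c + law.linear_slope
    else:
        attractor = law.attractor_intercept + law.attractor_slope * patient.duration
        new = law.ar_weight * patient.hba1c + (1.0 - law.ar_weight) * attractor
    patient.hba1c = max(0.0, new)
    return patient


def apply_intensification(
    patient: PatientState,
    policy: IntensificationPolicy,
    bmi_persistence: str = "revert_on_switch",
) -> PatientState:
    """Switch the patient to basal insulin and apply the HbA1c response.

    The policy's reduction is floored at zero (intensification never raises
    HbA1c).  Under ``revert_on_switch`` the first-year BMI benefit is lost
    and BMI returns to its baseline value.
    """
    patient.hba1c = max(0.0, patient.hba1c - policy.reduction(patient.hba1c))
    patient.therapy = "basal_insulin"
    patient.years_on_therapy = 0.0
    if bmi_persistence == "revert_on_switch":
        patient.bmi = patient.baseline_bmi
    return patient


def progress_secondary_factors(
    patient: PatientState, drift: SecondaryDrift
) -> PatientState:
    """Drift SBP and serum lipids one cycle toward their attractors.

    BMI is deliberately untouched here: it is piecewise-constant (treated
    value while on initial therapy, baseline after reversion) and only
    changes via :func:`apply_first_year_effects` and
    :func:`apply_intensification`.  eGFR is carried but not progressed.
    """
    for field_name, d in (("sbp", drift.sbp), ("tc", drift.tc), ("hdl", drift.hdl)):
        current = getattr(patient, field_name)
        new = d.ar_weight * current + (1.0 - d.ar_weight) * d.attractor
        setattr(patient, field_name, max(0.0, new))
    return patient
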