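"""Deterministic sensitivity-analysis suite and key-driver decomposition.

Each scenario is a pure transformation of the base-case study setup; all
scenarios run with common seeds so differences against the base case are
attributable to the changed input alone.  The key-driver runs apply the
intervention arm's treatment-effect differences one at a time, with every
other parameter set to the comparator arm's value.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import pandas as pd

from .engine import StudySetup, compare_arms, run_arm

_EFFECT_FIELDS = ("delta_hba1c", "delta_sbp", "delta_tc", "delta_hdl", "delta_bmi", "delta_egfr")


def _identity(s: StudySetup) -> StudySetup:
    return s


def _horizon(years: int) -> Callable[[StudySetup], StudySetup]:
    def f(s: StudySetup) -> StudySetup:
        s.config = s.config.model_copy(update={"horizon_years": years})
        return s
    return f


def _discount(rate: float) -> Callable[[StudySetup], StudySetup]:
    def f(s: StudySetup) -> StudySetup:
        s.config = s.config.model_copy(
            update={"discount_rate_costs": rate, "discount_rate_effects": rate}
        )
        return s
    return f


def _significant_only(s: StudySetup) -> StudySetup:
    # Non-significant intervention effects are set equal to the comparator's,
    # removing those between-arm differences.
    for name in _EFFECT_FIELDS:
        eff = getattr(s.intervention, name)
        if not eff.significant:
            comp = getattr(s.comparator, name)
            eff.mean, eff.se = comp.mean, comp.se
    return s


def _effect_ci(field_name: str, which: str) -> Callable[[StudySetup], StudySetup]:
    # Replace the intervention effect so the between-arm difference sits at
    # the bound of its 95% CI; "upper" is the bound favouring the
    # intervention (a larger reduction for HbA1c/BMI, where lower is better).
    def f(s: StudySetup) -> StudySetup:
        interv = getattr(s.intervention, field_name)
        comp = getattr(s.comparator, field_name)
        diff = interv.mean - comp.mean
        se_diff = math.hypot(interv.se, comp.se)
        shift = -1.96 * se_diff if which == "upper" else 1.96 * se_diff
        interv.mean = comp.mean + diff + shift
        return s
    return f


def _linear_switch_3y(s: StudySetup) -> StudySetup:
    s.config = s.config.model_copy(
        update={
            "hba1c_law": s.config.hba1c_law.model_copy(update={"kind": "linear"}),
            "switch_fixed_year": 3,
            "intensification_policy": s.config.intensification_policy.model_copy(
                update={"kind": "target_value", "target_hba1c": 7.0}
            ),
        }
    )
    return s


def _complication_costs(factor: float) -> Callable[[StudySetup], StudySetup]:
    def f(s: StudySetup) -> StudySetup:
        s.config = s.config.model_copy(update={"complication_cost_multiplier": factor})
        return s
    return f


def _config_update(**kw) -> Callable[[StudySetup], StudySetup]:
    def f(s: StudySetup) -> StudySetup:
        s.config = s.config.model_copy(update=kw)
        return s
    return f


def _comparator_price(factor: float) -> Callable[[StudySetup], StudySetup]:
    def f(s: StudySetup) -> StudySetup:
        s.cost_catalog = s.cost_catalog.model_copy(
            update={"comparator_price_multiplier": factor}
        )
        return s
    return f


def _no_switch_hba1c_change(s: StudySetup) -> StudySetup:
    s.config = s.config.model_copy(
        update={
            "intensification_policy": s.config.intensification_policy.model_copy(
                update={"kind": "none"}
            )
        }
    )
    return s


#: scenario tag -> (table row label, setup transformation)
SCENARIOS: dict[str, tuple[str, Callable[[StudySetup], StudySetup]]] = {
    "base_case": ("Base case", _identity),
    "significant_only": ("Statistically significant differences only", _significant_only),
    "horizon_35": ("35-year time horizon", _horizon(35)),
    "horizon_20": ("20-year time horizon", _horizon(20)),
    "horizon_10": ("10-year time horizon", _horizon(10)),
    "discount_0": ("0% discount rates", _discount(0.0)),
    "discount_3": ("3% discount rates", _discount(0.03)),
    "bmi_lifetime": (
        "BMI treatment effects maintained for patient lifetimes",
        _config_update(bmi_persistence="maintain_lifetime"),
    ),
    "no_switch_hba1c_change": (
        "UKPDS HbA1c progression with no changes on treatment switch",
        _no_switch_hba1c_change,
    ),
    "hba1c_upper_ci": (
        "Upper 95% CI of HbA1c estimated treatment difference",
        _effect_ci("delta_hba1c", "upper"),
    ),
    "hba1c_lower_ci": (
        "Lower 95% CI of HbA1c estimated treatment difference",
        _effect_ci("delta_hba1c", "lower"),
    ),
    "bmi_upper_ci": (
        "Upper 95% CI of BMI estimated treatment difference",
        _effect_ci("delta_bmi", "upper"),
    ),
    "bmi_lower_ci": (
        "Lower 95% CI of BMI estimated treatment difference",
        _effect_ci("delta_bmi", "lower"),
    ),
    "linear_switch_3y": (
        "Treatment switching at 3 years with linear HbA1c progression",
        _linear_switch_3y,
    ),
    "complication_costs_plus10": ("Costs of complications +10%", _complication_costs(1.1)),
    "complication_costs_minus10": ("Costs of complications -10%", _complication_costs(0.9)),
    "ukpds82": ("UKPDS 82 risk equations applied", _config_update(risk_set="ukpds82")),
    "lee_bmi_disutility": (
        "Lee et al. BMI disutility applied",
        _config_update(utility_model_bmi="lee"),
    ),
    "lauridsen_hypo": (
        "Lauridsen et al. diminishing hypoglycemia model applied",
        _config_update(hypo_disutility_model="lauridsen_diminishing"),
    ),
    "currie_hypo": (
        "Currie et al. hypoglycemia disutilities applied",
        _config_update(hypo_disutility_model="currie"),
    ),
    "comparator_price_minus10": ("Comparator price reduced by 10%", _comparator_price(0.9)),
}

#: key-driver tag -> effect fields whose between-arm difference is retained
KEY_DRIVERS: dict[str, tuple[str, ...]] = {
    "hba1c_only": ("delta_hba1c",),
    "sbp_only": ("delta_sbp",),
    "lipids_only": ("delta_tc", "delta_hdl"),
    "bmi_only": ("delta_bmi",),
    "hypo_only": (),  # hypoglycemia rates retained instead of an effect field
}


def apply_scenario(setup: StudySetup, tag: str) -> StudySetup:
    """Return a transformed copy of the setup for one scenario tag."""
    if tag not in SCENARIOS:
        raise ValueError(f"unknown scenario {tag!r}; valid tags: {sorted(SCENARIOS)}")
    _, transform = SCENARIOS[tag]
    return transform(setup.copy())


def apply_key_driver(setup: StudySetup, driver: str) -> StudySetup:
    """Retain only one treatment-effect difference; all else from the comparator."""
    if driver not in KEY_DRIVERS:
        raise ValueError(f"unknown key driver {driver!r}; valid: {sorted(KEY_DRIVERS)}")
    keep = KEY_DRIVERS[driver]
    s = setup.copy()
    for name in _EFFECT_FIELDS:
        if name not in keep:
            eff = getattr(s.comparator, name)
            setattr(s.intervention, name, eff.model_copy(deep=True))
    if driver != "hypo_only":
        s.intervention.nonsevere_hypo_rate = s.comparator.nonsevere_hypo_rate
        s.intervention.severe_hypo_rate = s.comparator.severe_hypo_rate
        s.intervention.nocturnal_fraction_nonsevere = s.comparator.nocturnal_fraction_nonsevere
        s.intervention.nocturnal_fraction_severe = s.comparator.nocturnal_fraction_severe
    return s


def run_scenario_suite(
    setup: StudySetup,
    suite: str = "table5",
    seed: Optional[int] = None,
    n_patients: Optional[int] = None,
    tags: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Run every scenario (or key-driver) with common seeds; one row per run.

    Columns: scenario tag, row label, per-arm discounted QALYs and costs,
    deltas, and the ICER (or dominance tag) for the comparison.
    """
    if suite == "table5":
        items = tags if tags is not None else list(SCENARIOS)
        make = lambda tag: (SCENARIOS[tag][0], apply_scenario(setup, tag))
    elif suite == "key_drivers":
        items = tags if tags is not None else list(KEY_DRIVERS)
        make = lambda tag: (f"Key driver: {tag}", apply_key_driver(setup, tag))
    else:
        raise ValueError(f"unknown suite {suite!r}; valid: 'table5', 'key_drivers'")
    rows = []
    for tag in items:
        label, s = make(tag)
        a = run_arm(s, "intervention", seed=seed, n_patients=n_patients)
        b = run_arm(s, "comparator", seed=seed, n_patients=n_patients)
        res = compare_arms(a, b)
        rows.append(
            {
                "scenario": tag,
                "label": label,
                "qalys_intervention": a.qalys_discounted,
                "qalys_comparator": b.qalys_discounted,
                "cost_intervention": a.cost_total_discounted,
                "cost_comparator": b.cost_total_discounted,
                "delta_qaly": res.delta_qaly,
                "delta_cost": res.delta_cost,
                "icer": res.icer,
                "dominance": res.dominance,
            }
        )
    return pd.DataFrame(rows)
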