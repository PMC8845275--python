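"""Risk-equation forms, mortality composition, event sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import logit

import diabsim as d
from diabsim.config import ConfigurationError
from diabsim.risk import (
    RiskCoefficientSet,
    TransitionTable,
    simulate_hypoglycemia_rates,
)

from conftest import flat_life_table, make_patient


def weibull_eq(shape, scale, **coefs):
    intercept = math.log(scale) if scale > 0 else -1e9  # exp(-1e9) == 0
    return RiskCoefficientSet(
        outcome="mi_event", form="weibull_ph", shape=shape,
        intercept=intercept, coefficients=coefs,
    )


class TestAnnualEventProbability:
    def test_constant_hazard_reduction(self):
        # shape 1 with exp(L)=0.02 is a constant hazard: p = 1 - exp(-0.02)
        eq = weibull_eq(1.0, 0.02)
        for duration in (0.0, 5.0, 40.0):
            p = d.annual_event_probability(eq, make_patient(duration=duration))
            assert p == pytest.approx(1.0 - math.exp(-0.02), abs=1e-12)

    def test_weibull_cumulative_hazard_difference(self):
        # shape 2, exp(L)=0.001, t=10: p = 1 - exp(-0.001*(121-100))
        eq = weibull_eq(2.0, 0.001)
        p = d.annual_event_probability(eq, make_patient(duration=10.0))
        assert p == pytest.approx(1.0 - math.exp(-0.021), abs=1e-12)
        # cross-check against numerical integration of the hazard function
        hazard = lambda t: 0.001 * 2.0 * t
        integral, _ = quad(hazard, 10.0, 11.0)
        assert p == pytest.approx(1.0 - math.exp(-integral), abs=1e-9)

    def test_monotone_in_hba1c_with_positive_coefficient(self):
        eq = weibull_eq(1.3, 0.01, hba1c=0.15)
        probs = [
            d.annual_event_probability(eq, make_patient(hba1c=h))
            for h in np.linspace(5.0, 12.0, 15)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_weibull_shape_one_equals_constant_rate(self):
        wb = weibull_eq(1.0, 1.0, hba1c=0.1, sbp10=0.05)
        cr = wb.model_copy(update={"form": "constant_rate"})
        for hba1c in (6.0, 8.14, 11.0):
            p = make_patient(hba1c=hba1c, duration=13.7)
            assert d.annual_event_probability(wb, p) == pytest.approx(
                d.annual_event_probability(cr, p), abs=1e-12
            )

    def test_logistic_form_is_expit(self):
        eq = RiskCoefficientSet(outcome="x", form="logistic", intercept=logit(0.2))
        assert d.annual_event_probability(eq, make_patient()) == pytest.approx(0.2)

    def test_missing_covariate_named_in_error(self):
        eq = weibull_eq(1.0, 0.01, not_a_covariate=1.0)
        with pytest.raises(ConfigurationError, match="not_a_covariate"):
            d.annual_event_probability(eq, make_patient())

    @given(
        hba1c=st.floats(4.0, 15.0),
        sbp=st.floats(80.0, 220.0),
        bmi=st.floats(15.0, 70.0),
        age=st.floats(18.0, 100.0),
        duration=st.floats(0.0, 60.0),
        smoker=st.booleans(),
        female=st.booleans(),
    )
    def test_probabilities_in_unit_interval_over_state_space(
        self, hba1c, sbp, bmi, age, duration, smoker, female
    ):
        patient = make_patient(
            hba1c=hba1c, sbp=sbp, bmi=bmi, age=age,
            duration=min(duration, age - 18.0) if age > 18 else 0.0,
            smoker=smoker, sex="female" if female else "male",
        )
        for eq in d.load_risk_set("ukpds68").values():
            p = d.annual_event_probability(eq, patient)
            assert 0.0 <= p <= 1.0


class TestAnnualDeathProbability:
    def test_independent_competing_risks_product(self):
        # q_b = 0.01 and one event with case fatality 0.2: 1 - 0.99*0.8
        fatality = RiskCoefficientSet(
            outcome="fatality:mi_event", form="logistic", intercept=float(logit(0.2))
        )
        q = d.annual_death_probability(
            make_patient(age=40.0), flat_life_table(0.01), [fatality], ["mi_event"]
        )
        assert q == pytest.approx(0.208, abs=1e-12)

    def test_no_hazard_sources_gives_zero(self):
        q = d.annual_death_probability(
            make_patient(age=40.0), flat_life_table(0.0), [], []
        )
        assert q == 0.0

    def test_age_beyond_table_is_certain_death(self):
        q = d.annual_death_probability(
            make_patient(age=120.0), flat_life_table(0.0), [], []
        )
        assert q == 1.0

    def test_excess_mortality_applies_to_active_state(self):
        excess = RiskCoefficientSet(
            outcome="excess:chf", form="logistic", intercept=float(logit(0.1))
        )
        patient = make_patient(age=40.0, chf=True)
        q = d.annual_death_probability(patient, flat_life_table(0.0), [excess], [])
        assert q == pytest.approx(0.1)
        # state not active -> no contribution
        q2 = d.annual_death_probability(
            make_patient(age=40.0), flat_life_table(0.0), [excess], []
        )
        assert q2 == 0.0


class TestSampleCycleEvents:
    def test_zero_probabilities_leave_state_unchanged(self, rng):
        eqs = {"mi_event": weibull_eq(1.0, 0.0)}  # exp(L)=0 -> p=0
        patient = make_patient()
        before = [getattr(patient, f) for f in ("mi_history", "chf", "foot_stage")]
        d.sample_cycle_events(patient, eqs, [], rng)
        after = [getattr(patient, f) for f in ("mi_history", "chf", "foot_stage")]
        assert before == after
        assert patient.events_this_cycle == []

    def test_forced_amputation(self, rng):
        eqs = {"amputation_event": RiskCoefficientSet(
            outcome="amputation_event", form="logistic", intercept=50.0)}
        patient = make_patient()
        d.sample_cycle_events(patient, eqs, [], rng)
        assert patient.foot_stage == "amputated"
        assert "amputation_event" in patient.events_this_cycle

    def test_dead_patient_rejected(self, rng):
        patient = make_patient()
        patient.alive = False
        with pytest.raises(ValueError, match="dead"):
            d.sample_cycle_events(patient, {}, [], rng)

    def test_incidence_matches_probability(self, rng):
        # empirical event frequency at fixed state matches the per-cycle
        # probability within binomial sampling error
        eq = weibull_eq(1.0, 0.05)
        p_true = 1.0 - math.exp(-0.05)
        hits = 0
        n = 4000
        for _ in range(n):
            patient = make_patient()
            d.sample_cycle_events(patient, {"mi_event": eq}, [], rng)
            hits += patient.mi_history
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert hits / n == pytest.approx(p_true, abs=4 * se)

    def test_hypoglycemia_rate_recovery(self):
        ns, sev = simulate_hypoglycemia_rates(4.08, 0.10, 10_000, seed=42)
        assert ns == pytest.approx(4.08, rel=0.02)
        assert sev == pytest.approx(0.10, rel=0.10)

    def test_risk_set_swap_changes_only_coefficients(self):
        # evaluating the alternative catalog's equations goes through the
        # identical code path: a copied catalog gives identical probabilities
        base = d.load_risk_set("ukpds68")
        relabelled = {
            tag: eq.model_copy(update={"source_label": "swapped"})
            for tag, eq in base.items()
        }
        patient = make_patient()
        for tag in base:
            assert d.annual_event_probability(base[tag], patient) == \
                d.annual_event_probability(relabelled[tag], patient)


class TestTransitionTables:
    def test_backward_transition_rejected(self):
        with pytest.raises(ValueError, match="backward"):
            TransitionTable(
                name="retinopathy", states=["none", "bdr"],
                transitions=[{"frm": "bdr", "to": "none", "probability": 0.1}],
            )

    def test_forced_chain_advance_single_step(self, rng):
        tables = d.load_transition_tables()
        retino = next(t for t in tables if t.name == "retinopathy")
        forced = retino.model_copy(deep=True)
        for tr in forced.transitions:
            tr.probability = 1.0
        patient = make_patient()
        d.sample_cycle_events(patient, {}, [forced], rng)
        assert patient.retinopathy_stage == "bdr"  # at most one step per cycle

    def test_hba1c_relative_risk_raises_probability(self):
        tables = d.load_transition_tables()
        neph = next(t for t in tables if t.name == "nephropathy")
        tr = neph.transitions[0]
        low = neph.effective_probability(tr, make_patient(hba1c=6.0))
        high = neph.effective_probability(tr, make_patient(hba1c=10.0))
        assert high > low

    def test_gate_multiplier(self):
        tables = d.load_transition_tables()
        foot = next(t for t in tables if t.name == "foot_ulcer")
        tr = foot.transitions[0]
        without = foot.effective_probability(tr, make_patient(hba1c=7.0))
        with_neuropathy = foot.effective_probability(
            tr, make_patient(hba1c=7.0, neuropathy=True)
        )
        assert with_neuropathy == pytest.approx(5.0 * without)
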