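"""Synthetic patient-cohort generation and the placeholder cost catalog.

Cohorts are drawn patient-by-patient from the published baseline means and
standard deviations: continuous characteristics from truncated normal
distributions (truncation at plausible physiological bounds), sex and
smoking status as independent Bernoulli draws.  No correlation structure is
imposed (none is published).  The same ``(spec, n, seed)`` triple always
produces a bitwise-identical cohort.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import CohortSpec, Dist, PatientState
from .treatment import CostCatalog

#: plausibility truncation bounds for sampled characteristics
TRUNCATION_BOUNDS = {
    "start_age": (18.0, 100.0),
    "diabetes_duration": (0.0, np.inf),
    "hba1c": (4.0, 15.0),
    "sbp": (80.0, 220.0),
    "bmi": (15.0, 70.0),
    "total_cholesterol": (80.0, 400.0),
    "hdl": (15.0, 120.0),
    "egfr": (15.0, 200.0),
}


def _draw(dist: Dist, bounds: tuple[float, float], n: int, rng: np.random.Generator) -> np.ndarray:
    if dist.sd == 0.0:
        return np.full(n, dist.mean)
    lo, hi = bounds
    a, b = (lo - dist.mean) / dist.sd, (hi - dist.mean) / dist.sd
    return truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd, size=n, random_state=rng)


def sample_cohort(spec: CohortSpec, n: int, seed: int) -> list[PatientState]:
    """Draw ``n`` independent patients from the cohort specification.

    Duration is capped at the sampled age minus 18 so no patient is
    diagnosed in childhood.  ``baseline_bmi`` records the sampled BMI for
    later reversion on treatment intensification; all patients start on
    initial therapy.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    age = _draw(spec.start_age, TRUNCATION_BOUNDS["start_age"], n, rng)
    duration = _draw(spec.diabetes_duration, TRUNCATION_BOUNDS["diabetes_duration"], n, rng)
    duration = np.minimum(duration, np.maximum(0.0, age - 18.0))
    male = rng.random(n) < spec.proportion_male
    hba1c = _draw(spec.hba1c, TRUNCATION_BOUNDS["hba1c"], n, rng)
    sbp = _draw(spec.sbp, TRUNCATION_BOUNDS["sbp"], n, rng)
    bmi = _draw(spec.bmi, TRUNCATION_BOUNDS["bmi"], n, rng)
    tc = _draw(spec.total_cholesterol, TRUNCATION_BOUNDS["total_cholesterol"], n, rng)
    hdl = _draw(spec.hdl, TRUNCATION_BOUNDS["hdl"], n, rng)
    egfr = _draw(spec.egfr, TRUNCATION_BOUNDS["egfr"], n, rng)
    smoker = rng.random(n) < spec.proportion_smoker
    return [
        PatientState(
            age=float(age[i]),
            sex="male" if male[i] else "female",
            duration=float(duration[i]),
            hba1c=float(hba1c[i]),
            sbp=float(sbp[i]),
            tc=float(tc[i]),
            hdl=float(hdl[i]),
            bmi=float(bmi[i]),
            egfr=float(egfr[i]),
            smoker=bool(smoker[i]),
            baseline_bmi=float(bmi[i]),
        )
        for i in range(n)
    ]


#: documented CSV column order for cohort export
COHORT_COLUMNS = [
    "age",
    "sex",
    "duration",
    "hba1c",
    "sbp",
    "tc",
    "hdl",
    "bmi",
    "egfr",
    "smoker",
]


def cohort_to_frame(cohort: list[PatientState]) -> pd.DataFrame:
    """One row per patient, columns in :data:`COHORT_COLUMNS` order."""
    return pd.DataFrame(
        [[getattr(p, c) for c in COHORT_COLUMNS] for p in cohort], columns=COHORT_COLUMNS
    )


def make_placeholder_cost_catalog(scale: float = 1.0) -> CostCatalog:
    """Schema-complete placeholder cost catalog, every entry scaled by ``scale``.

    The analysis's real unit costs (national tariffs and pharmacy prices)
    are not published; this catalog carries one documented placeholder value
    per therapy, complication event, chronic state-year, and management
    item, in the exact schema a user would fill with real tariffs.  Every
    lifetime cost category (treatment, management, hypoglycemia,
    cardiovascular, renal, ophthalmic, neuropathy/foot) has at least one
    nonzero entry at ``scale=1``; all entries are linear in ``scale``.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    s = float(scale)
    return CostCatalog(
        currency_label="placeholder currency units (scale {:g})".format(s),
        therapy_daily_cost={
            "oral_semaglutide": 3.00 * s,
            "empagliflozin": 1.50 * s,
            "dulaglutide": 3.00 * s,
        },
        insulin_cost_per_iu=0.02 * s,
        needle_cost=0.10 * s,
        smbg_strip_cost=0.30 * s,
        event_costs={
            "mi_event": 5000.0 * s,
            "stroke_event": 7000.0 * s,
            "chf_event": 2000.0 * s,
            "angina_event": 1000.0 * s,
            "pvd_event": 800.0 * s,
            "renal_failure_event": 3000.0 * s,
            "amputation_event": 10000.0 * s,
            "ulcer_event": 1500.0 * s,
            "macular_edema_event": 500.0 * s,
            "cataract_event": 1500.0 * s,
            "hypo_nonsevere": 5.0 * s,
            "hypo_severe": 400.0 * s,
        },
        state_annual_costs={
            "post_mi": 800.0 * s,
            "angina": 700.0 * s,
            "chf": 2500.0 * s,
            "post_stroke": 2000.0 * s,
            "pvd": 600.0 * s,
            "microalbuminuria": 50.0 * s,
            "gross_proteinuria": 300.0 * s,
            "hemodialysis": 35000.0 * s,
            "peritoneal_dialysis": 30000.0 * s,
            "renal_transplant": 8000.0 * s,
            "bdr": 100.0 * s,
            "pdr": 800.0 * s,
            "macular_edema": 700.0 * s,
            "svl": 1200.0 * s,
            "cataract": 50.0 * s,
            "neuropathy": 400.0 * s,
            "healed_ulcer": 100.0 * s,
            "active_ulcer": 2500.0 * s,
            "post_amputation": 1500.0 * s,
        },
        management_annual_cost=600.0 * s,
        comparator_price_multiplier=1.0,
    )
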