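import numpy as np
import pytest
from hypothesis import settings

import diabsim as d
from diabsim.config import LifeTable, LifeTableRow, PatientState

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_patient(**kw) -> PatientState:
    base = dict(
        age=57.63, sex="male", duration=7.0, hba1c=8.14, sbp=132.15,
        tc=180.0, hdl=45.0, bmi=32.82, egfr=90.0, smoker=False,
        baseline_bmi=32.82,
    )
    base.update(kw)
    return PatientState(**base)


def flat_life_table(q: float) -> LifeTable:
    rows = [
        LifeTableRow(age_lo=0.0, age_hi=110.0, sex=s, q=q) for s in ("male", "female")
    ]
    return LifeTable(rows=rows)


@pytest.fixture(scope="session")
def p2_setup() -> d.StudySetup:
    return d.load_study("pioneer2")


@pytest.fixture(scope="session")
def nma_setup() -> d.StudySetup:
    return d.load_study("nma")


@pytest.fixture(scope="session")
def utilities():
    return d.load_utility_catalog()


@pytest.fixture(scope="session")
def costs():
    return d.make_placeholder_cost_catalog(1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
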