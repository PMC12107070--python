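import datetime as dt

import pytest

from lupus_t2t.cohort import VisitRecord
from lupus_t2t.imputation import load_growth_reference
from lupus_t2t.simulate import CohortConfig, generate_cohort
from lupus_t2t.targets import default_definitions


@pytest.fixture(scope="session")
def growth_ref():
    return load_growth_reference()


@pytest.fixture(scope="session")
def definitions():
    return default_definitions()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    cfg = CohortConfig(n_patients=60, seed=7)
    return generate_cohort(cfg)


def make_visit(
    patient_id="P1",
    visit_date=dt.date(2018, 1, 1),
    age=12.0,
    weight=50.0,
    items=None,
    pga=0.0,
    grades=None,
    sdi=0,
    pred=0.0,
    iv=False,
    imsn="none",
    **kwargs,
) -> VisitRecord:
    return VisitRecord(
        patient_id=patient_id,
        visit_date=visit_date,
        age_at_visit=age,
        weight_kg=weight,
        weight_provenance="measured" if weight is not None else "missing",
        sledai_items=dict(items or {}),
        pga=pga,
        pbilag_grades=dict(grades or {}),
        sdi=sdi,
        prednisolone_mg_day=pred,
        iv_methylpred=iv,
        imsn_change=imsn,
        **kwargs,
    )
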