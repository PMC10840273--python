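import datetime as dt

import pytest

from cvcsurv import (
    Admission,
    BloodCultureDraw,
    CohortBundle,
    CommensalList,
    Isolate,
    OrganismClass,
    Site,
    SurveillanceConfig,
    classify_isolate,
)
from cvcsurv.simulate import CohortSimConfig, generate_cohort, implant_edge_cases

T0 = dt.datetime(2018, 3, 1, 8, 0)


@pytest.fixture(scope="session")
def config():
    return SurveillanceConfig()


@pytest.fixture(scope="session")
def commensals():
    return CommensalList.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact generated cohort with known ground truth."""
    cfg = CohortSimConfig(n_admissions=400, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def edge_cohort():
    """Small cohort with every boundary fixture appended."""
    cfg = CohortSimConfig(n_admissions=150, seed=5)
    bundle, truth = generate_cohort(cfg)
    return implant_edge_cases(bundle, truth)


def make_draw(
    commensal_list,
    draw_id,
    admission_id,
    ts,
    codes=(),
    site=Site.UNSPECIFIED,
    ttp=None,
):
    isolates = tuple(Isolate(c, classify_isolate(c, commensal_list)) for c in codes)
    return BloodCultureDraw(draw_id, admission_id, ts, site, isolates, ttp)


def make_bundle(commensal_list, admissions, draws=(), tips=(), vitals=(), refs=None):
    return CohortBundle(
        admissions=list(admissions),
        blood_cultures=list(draws),
        tip_cultures=list(tips),
        vitals=list(vitals),
        commensal_list=commensal_list,
        reference_labels=refs,
    ).validate()


@pytest.fixture
def one_admission():
    return Admission("A1", "P1", T0, T0 + dt.timedelta(days=10))
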