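import pytest

from ugib_scores.cohort import PatientRecord
from ugib_scores.synthetic import SyntheticCohortConfig, generate_cohort

#: A complete, clinically unremarkable admission; tests override fields.
BASELINE = dict(
    id="pt-baseline",
    outcome_death=False,
    age=50,
    sex="male",
    sbp=120.0,
    heart_rate=70.0,
    hemoglobin=15.0,
    urea=30.0,
    creatinine=1.0,
    albumin=4.0,
    inr=1.0,
    bilirubin=0.8,
    syncope=False,
    melena=False,
    hematochezia=False,
    hematemesis="none",
    altered_mental_status=False,
    general_condition="good",
    asa_class=1,
    antiplatelet=False,
    anticoagulant=False,
    nsaid=False,
    comorbidities=frozenset(),
    comorbidity_count=0,
    comorbidity_severity="none",
    ascites="none",
    encephalopathy="none",
    covid_status="prepandemic",
    period="prepandemic",
    etiology_group="no_endoscopy",
)


def make_record(**overrides) -> PatientRecord:
    data = dict(BASELINE)
    data.update(overrides)
    return PatientRecord(**data)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """Default-mix synthetic cohort, small enough for fast unit tests."""
    return generate_cohort(SyntheticCohortConfig(n=800, seed=11))


@pytest.fixture(scope="session")
def noendo_cohort_4k():
    """No-endoscopy-only cohort used by generator property tests."""
    cfg = SyntheticCohortConfig(
        n=4000,
        seed=5,
        group_mix={"nonvariceal": 0.0, "variceal": 0.0, "no_endoscopy": 1.0},
    )
    return generate_cohort(cfg)
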