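import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugib_scores.cohort import KNOWN_COMORBIDITIES
from ugib_scores.scores import (
    HIGHER_IS_WORSE,
    LOWER_IS_WORSE,
    SCORE_FUNCTIONS,
    SCORE_RANGES,
    score_all,
)

from conftest import make_record
from score_examples import GOLDEN_EXAMPLES


@pytest.mark.parametrize(
    "name,overrides,expected",
    GOLDEN_EXAMPLES,
    ids=[f"{n}-{e}" for n, _, e in GOLDEN_EXAMPLES],
)
def test_golden_examples(name, overrides, expected):
    """Each score reproduces its hand-summed point-table examples."""
    result = SCORE_FUNCTIONS[name](make_record(**overrides))
    assert result.usable
    assert result.value == expected
    assert result.value == sum(result.components.values())


record_strategy = st.builds(
    make_record,
    age=st.integers(16, 99),
    sex=st.sampled_from(["male", "female"]),
    sbp=st.floats(50, 220),
    heart_rate=st.floats(40, 190),
    hemoglobin=st.floats(3, 18),
    urea=st.floats(5, 400),
    creatinine=st.floats(0.3, 12),
    albumin=st.floats(1.2, 5.5),
    inr=st.floats(0.8, 9),
    syncope=st.booleans(),
    melena=st.booleans(),
    hematemesis=st.sampled_from(["none", "coffee_ground", "red_blood"]),
    altered_mental_status=st.booleans(),
    general_condition=st.sampled_from(["poor", "intermediate", "good"]),
    asa_class=st.integers(1, 5),
    antiplatelet=st.booleans(),
    comorbidities=st.frozensets(st.sampled_from(sorted(KNOWN_COMORBIDITIES))),
    comorbidity_count=st.integers(0, 12),
    comorbidity_severity=st.sampled_from(["none", "chronic", "acute"]),
)


@settings(max_examples=200, derandomize=True)
@given(record=record_strategy)
def test_scores_within_documented_ranges(record):
    """Every usable score stays inside its closed range, its value equals
    the component sum, and only the T-score is lower-is-worse."""
    for name, result in score_all(record).items():
        assert result.usable, (name, result.missing)
        lo, hi = SCORE_RANGES[name]
        assert lo <= result.value <= hi, (name, result.value)
        assert result.value == sum(result.components.values())
        expected_dir = LOWER_IS_WORSE if name == "t_score" else HIGHER_IS_WORSE
        assert result.direction == expected_dir


@settings(max_examples=200, derandomize=True)
@given(record=record_strategy)
def test_modified_n_never_exceeds_n(record):
    n = SCORE_FUNCTIONS["n_score"](record).value
    mn = SCORE_FUNCTIONS["modified_n_score"](record).value
    assert mn <= n
    if record.hematemesis.value != "coffee_ground":
        assert mn == n


# single-field worsening transformations; each must not decrease any
# higher-is-worse score and must not increase the T-score
_WORSENINGS = [
    ("hemoglobin", lambda r: dict(hemoglobin=max(3.0, r.hemoglobin - 3.0))),
    ("sbp", lambda r: dict(sbp=max(50.0, r.sbp - 25.0))),
    ("heart_rate", lambda r: dict(heart_rate=min(190.0, r.heart_rate + 30.0))),
    ("urea", lambda r: dict(urea=min(400.0, r.urea * 2))),
    ("albumin", lambda r: dict(albumin=max(1.2, r.albumin - 1.0))),
    ("age", lambda r: dict(age=min(99, r.age + 15))),
    ("syncope", lambda r: dict(syncope=True)),
    ("altered_mental_status", lambda r: dict(altered_mental_status=True)),
    ("general_condition", lambda r: dict(general_condition="poor")),
    ("asa_class", lambda r: dict(asa_class=5)),
]


@settings(max_examples=100, derandomize=True)
@given(record=record_strategy, idx=st.integers(0, len(_WORSENINGS) - 1))
def test_single_component_worsening_is_monotone(record, idx):
    _, transform = _WORSENINGS[idx]
    worse = make_record(**{**record.model_dump(exclude={"id"}), "id": "w", **transform(record)})
    before = score_all(record)
    after = score_all(worse)
    for name in SCORE_FUNCTIONS:
        if name == "t_score":
            assert after[name].value <= before[name].value
        else:
            assert after[name].value >= before[name].value


def test_missing_inputs_flag_score_unusable():
    rec = make_record(albumin=None)
    results = score_all(rec)
    for name in ("aim65", "map_score", "inbs"):
        assert not results[name].usable
        assert "albumin" in results[name].missing
        assert results[name].value is None
    for name in set(SCORE_FUNCTIONS) - {"aim65", "map_score", "inbs"}:
        assert results[name].usable, name


def test_score_all_returns_all_thirteen():
    results = score_all(make_record())
    assert set(results) == set(SCORE_FUNCTIONS)
    assert len(results) == 13
    assert all(r.usable for r in results.values())


def test_inbs_worked_example_appears_in_batch():
    rec = make_record(
        age=68,
        comorbidities=frozenset({"liver_disease_cirrhosis"}),
        urea=72.1,
        albumin=2.8,
        creatinine=1.36,
    )
    assert score_all(rec)["inbs"].value == 7


@pytest.mark.parametrize(
    "urea,expected_pts",
    [(38.9, 0), (39.0, 2), (47.9, 2), (48.0, 3), (59.9, 3), (60.0, 4), (149.9, 4), (150.0, 6)],
)
def test_gbs_urea_bin_edges_half_open(urea, expected_pts):
    res = SCORE_FUNCTIONS["glasgow_blatchford"](make_record(urea=urea))
    assert res.components["urea"] == expected_pts


@pytest.mark.parametrize(
    "sex,hb,expected_pts",
    [("male", 13.0, 0), ("male", 12.5, 1), ("male", 11.9, 3), ("male", 9.9, 6),
     ("female", 12.0, 0), ("female", 11.9, 1), ("female", 9.9, 6)],
)
def test_gbs_hemoglobin_bins_by_sex(sex, hb, expected_pts):
    res = SCORE_FUNCTIONS["glasgow_blatchford"](make_record(sex=sex, hemoglobin=hb))
    assert res.components["hemoglobin"] == expected_pts


def test_rockall_comorbidity_tiers_not_additive():
    rec = make_record(
        comorbidities=frozenset({"cardiac_failure", "renal_failure"}), age=45
    )
    res = SCORE_FUNCTIONS["rockall_pre"](rec)
    assert res.components["comorbidity"] == 3
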