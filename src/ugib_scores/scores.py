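"""Pre-endoscopic prognostic scores for upper gastrointestinal bleeding.

Thirteen point-based scores computable from clinical and laboratory data
alone (no endoscopy): Glasgow-Blatchford (GBS) and its modified form,
pre-endoscopic Rockall, pre-endoscopic Baylor, AIM65, T-score, N-score
and a modified N-score that grades hematemesis type, H3B2, MAP (ASH),
Iino, the International Bleeding Score (INBS/ABC), and the Charlson
comorbidity index.

Each calculator is a pure function ``PatientRecord -> ScoreResult``.
When a required input is missing the result is flagged unusable with the
missing fields named, never silently zeroed.  All threshold tables are
module-level constants so every bin edge can be enumerated in tests.

Bin conventions: printed integer ranges are half-open on the right
(urea 39-47 means [39, 48)), matching the original SI-unit bin edges of
the Glasgow-Blatchford score; direction is higher-is-worse for every
score except the T-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .cohort import Hematemesis, PatientRecord, Sex
from .units import bun_from_urea, creatinine_umol_from_mg, egfr_ckd_epi_2021, urea_mmol_from_mg

__all__ = [
    "ScoreResult",
    "glasgow_blatchford",
    "modified_glasgow_blatchford",
    "rockall_pre",
    "baylor_pre",
    "aim65",
    "t_score",
    "n_score",
    "modified_n_score",
    "h3b2",
    "map_score",
    "iino_score",
    "inbs",
    "charlson_index",
    "score_all",
    "SCORE_FUNCTIONS",
    "SCORE_RANGES",
    "HIGHER_IS_WORSE",
    "LOWER_IS_WORSE",
]

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"


@dataclass(frozen=True)
class ScoreResult:
    """A named score value with per-component breakdown.

    ``value`` is ``None`` and ``usable`` is False when any required
    input is missing; ``missing`` then names the absent fields.
    The value always equals the sum of ``components``.
    """

    name: str
    value: Optional[int]
    direction: str = HIGHER_IS_WORSE
    components: dict[str, int] = field(default_factory=dict)
    usable: bool = True
    missing: tuple[str, ...] = ()

    def __post_init__(self):
        if self.usable and self.value != sum(self.components.values()):
            raise ValueError(
                f"{self.name}: value {self.value} != component sum "
                f"{sum(self.components.values())}"
            )


def _missing(record: PatientRecord, fields: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(f for f in fields if getattr(record, f) is None)


def _unusable(name: str, direction: str, missing: tuple[str, ...]) -> ScoreResult:
    return ScoreResult(name, None, direction, {}, usable=False, missing=missing)


def _bin(value: float, bins: tuple[tuple[float, float, int], ...]) -> int:
    """Points for the half-open bin [lo, hi) containing value; 0 outside."""
    for lo, hi, pts in bins:
        if lo <= value < hi:
            return pts
    return 0


INF = math.inf

# --- Glasgow-Blatchford -------------------------------------------------

GBS_UREA_BINS = ((39, 48, 2), (48, 60, 3), (60, 150, 4), (150, INF, 6))
GBS_HB_BINS_MALE = ((12, 13, 1), (10, 12, 3), (0, 10, 6))
GBS_HB_BINS_FEMALE = ((10, 12, 1), (0, 10, 6))
GBS_SBP_BINS = ((100, 110, 1), (90, 100, 2), (0, 90, 3))

_GBS_FIELDS = ("urea", "hemoglobin", "sbp", "heart_rate", "sex")
_LIVER_CODES = (
    "liver_disease_cirrhosis",
    "mild_liver_disease",
    "moderate_severe_liver_disease",
)
_CARDIAC_FAILURE_CODES = ("cardiac_failure", "congestive_heart_failure")


def _gbs_core(record: PatientRecord) -> dict[str, int]:
    hb_bins = GBS_HB_BINS_MALE if record.sex == Sex.male else GBS_HB_BINS_FEMALE
    return {
        "urea": _bin(record.urea, GBS_UREA_BINS),
        "hemoglobin": _bin(record.hemoglobin, hb_bins),
        "sbp": _bin(record.sbp, GBS_SBP_BINS),
        "pulse": 1 if record.heart_rate > 100 else 0,
    }


def glasgow_blatchford(record: PatientRecord) -> ScoreResult:
    """Glasgow-Blatchford score, range 0-23."""
    name = "glasgow_blatchford"
    miss = _missing(record, _GBS_FIELDS + ("melena", "syncope", "comorbidities"))
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = _gbs_core(record)
    comp["melena"] = 1 if record.melena else 0
    comp["syncope"] = 2 if record.syncope else 0
    comp["liver_disease"] = 2 if record.has_comorbidity(*_LIVER_CODES) else 0
    comp["cardiac_failure"] = 2 if record.has_comorbidity(*_CARDIAC_FAILURE_CODES) else 0
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


def modified_glasgow_blatchford(record: PatientRecord) -> ScoreResult:
    """GBS restricted to urea, hemoglobin, blood pressure and pulse; 0-16."""
    name = "modified_glasgow_blatchford"
    miss = _missing(record, _GBS_FIELDS)
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = _gbs_core(record)
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- pre-endoscopic Rockall --------------------------------------------

ROCKALL_AGE_BINS = ((60, 80, 1), (80, INF, 2))


def rockall_pre(record: PatientRecord) -> ScoreResult:
    """Clinical (pre-endoscopic) Rockall score, range 0-7.

    Comorbidity tiers are non-additive: the highest applicable tier is
    scored (renal/liver failure or disseminated malignancy at 3 points
    dominate cardiac failure / coronary ischemia at 2).
    """
    name = "rockall_pre"
    miss = _missing(record, ("age", "heart_rate", "sbp", "comorbidities"))
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = {"age": _bin(record.age, ROCKALL_AGE_BINS)}
    if record.sbp < 100:
        comp["shock"] = 2
    elif record.heart_rate >= 100:
        comp["shock"] = 1
    else:
        comp["shock"] = 0
    if record.has_comorbidity(
        "renal_failure",
        "moderate_severe_renal_disease",
        "liver_disease_cirrhosis",
        "moderate_severe_liver_disease",
        "disseminated_malignancy",
        "metastatic_solid_tumor",
    ):
        comp["comorbidity"] = 3
    elif record.has_comorbidity(
        *_CARDIAC_FAILURE_CODES, "ischemic_heart_disease", "myocardial_infarction"
    ):
        comp["comorbidity"] = 2
    else:
        comp["comorbidity"] = 0
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- pre-endoscopic Baylor ---------------------------------------------

BAYLOR_AGE_BINS = ((30, 50, 1), (50, 60, 2), (60, 70, 3), (70, INF, 5))
BAYLOR_DISEASE_COUNT_BINS = ((1, 3, 1), (3, 5, 4), (5, INF, 5))


def baylor_pre(record: PatientRecord) -> ScoreResult:
    """Pre-endoscopic Baylor bleeding score, range 0-15.

    Disease severity: acute (5) dominates chronic (4) when both apply.
    """
    name = "baylor_pre"
    miss = _missing(
        record, ("age", "comorbidity_count", "comorbidity_severity")
    )
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    sev = {"none": 0, "chronic": 4, "acute": 5}[record.comorbidity_severity.value]
    comp = {
        "age": _bin(record.age, BAYLOR_AGE_BINS),
        "disease_count": _bin(record.comorbidity_count, BAYLOR_DISEASE_COUNT_BINS),
        "disease_severity": sev,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- AIM65 --------------------------------------------------------------


def aim65(record: PatientRecord) -> ScoreResult:
    """AIM65: albumin, INR, mental status, age > 65, systolic BP; 0-5."""
    name = "aim65"
    miss = _missing(record, ("age", "sbp", "altered_mental_status", "albumin", "inr"))
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = {
        "albumin_lt_3": 1 if record.albumin < 3.0 else 0,
        "inr_gt_1_5": 1 if record.inr > 1.5 else 0,
        "altered_mental_status": 1 if record.altered_mental_status else 0,
        "age_gt_65": 1 if record.age > 65 else 0,
        "sbp_lt_90": 1 if record.sbp < 90 else 0,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- T-score ------------------------------------------------------------


def t_score(record: PatientRecord) -> ScoreResult:
    """T-score, range 4-12; the only lower-is-worse score here.

    The printed hemoglobin rows (<=8 / 9-10 / >10) leave (8, 9) uncovered;
    the middle band is read as (8, 10] so coverage is contiguous.
    """
    name = "t_score"
    miss = _missing(record, ("heart_rate", "sbp", "hemoglobin", "general_condition"))
    if miss:
        return _unusable(name, LOWER_IS_WORSE, miss)
    hr = record.heart_rate
    pulse = 1 if hr > 110 else (2 if hr >= 90 else 3)
    sbp = 1 if record.sbp < 90 else (2 if record.sbp <= 110 else 3)
    hb = record.hemoglobin
    hbp = 1 if hb <= 8 else (2 if hb <= 10 else 3)
    cond = {"poor": 1, "intermediate": 2, "good": 3}[record.general_condition.value]
    comp = {"pulse": pulse, "sbp": sbp, "hemoglobin": hbp, "general_condition": cond}
    return ScoreResult(name, sum(comp.values()), LOWER_IS_WORSE, comp)


# --- N-score family -----------------------------------------------------

BUN_THRESHOLD = 22.4  # mg/dL; corresponds to urea ~48 mg/dL


def _n_core(record: PatientRecord) -> dict[str, int]:
    if record.creatinine == 0:
        raise ValueError("creatinine must be positive for BUN/creatinine ratio")
    bun = bun_from_urea(record.urea)
    return {
        "syncope": 3 if record.syncope else 0,
        "bun": 1 if bun >= BUN_THRESHOLD else 0,
        "bun_creatinine_ratio": 1 if bun / record.creatinine >= 30 else 0,
    }


_N_FIELDS = ("syncope", "hematemesis", "urea", "creatinine")


def n_score(record: PatientRecord) -> ScoreResult:
    """N-score: syncope, hematemesis, BUN, BUN/creatinine ratio; 0-7."""
    name = "n_score"
    miss = _missing(record, _N_FIELDS)
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = _n_core(record)
    comp["hematemesis"] = 2 if record.hematemesis != Hematemesis.none else 0
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


def modified_n_score(record: PatientRecord) -> ScoreResult:
    """N-score with hematemesis graded: red blood 2, coffee-ground 1; 0-7."""
    name = "modified_n_score"
    miss = _missing(record, _N_FIELDS)
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = _n_core(record)
    comp["hematemesis"] = {"none": 0, "coffee_ground": 1, "red_blood": 2}[
        record.hematemesis.value
    ]
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- H3B2 ---------------------------------------------------------------


def h3b2(record: PatientRecord) -> ScoreResult:
    """H3B2: hematemesis, heart rate, blood pressure, hemoglobin, BUN; 0-6."""
    name = "h3b2"
    miss = _missing(record, ("hematemesis", "heart_rate", "sbp", "hemoglobin", "urea"))
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = {
        "hematemesis": 1 if record.hematemesis != Hematemesis.none else 0,
        "heart_rate_ge_100": 1 if record.heart_rate >= 100 else 0,
        "sbp_le_100": 1 if record.sbp <= 100 else 0,
        "hb_le_10": 1 if record.hemoglobin <= 10 else 0,
        "bun_ge_22_4": 2 if bun_from_urea(record.urea) >= BUN_THRESHOLD else 0,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- MAP (ASH) ----------------------------------------------------------


def map_score(record: PatientRecord) -> ScoreResult:
    """MAP (ASH) score, range 0-9."""
    name = "map_score"
    miss = _missing(
        record,
        ("altered_mental_status", "asa_class", "heart_rate", "sbp", "hemoglobin", "albumin"),
    )
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    comp = {
        "consciousness": 1 if record.altered_mental_status else 0,
        "asa_gt_2": 1 if record.asa_class > 2 else 0,
        "heart_rate_gt_100": 1 if record.heart_rate > 100 else 0,
        "sbp_lt_90": 2 if record.sbp < 90 else 0,
        "hb_lt_10": 2 if record.hemoglobin < 10 else 0,
        "albumin_lt_2_5": 2 if record.albumin < 2.5 else 0,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- Iino ---------------------------------------------------------------


def iino_score(record: PatientRecord) -> ScoreResult:
    """Iino (Hirosaki) score, range -4..10.

    Renal function enters through the race-free CKD-EPI 2021 eGFR;
    preserved filtration (>= 60 mL/min/1.73 m^2) and antiplatelet use
    subtract points.
    """
    name = "iino_score"
    miss = _missing(
        record,
        ("sbp", "syncope", "hematemesis", "hemoglobin", "urea", "creatinine", "age", "sex", "antiplatelet"),
    )
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    egfr = egfr_ckd_epi_2021(record.creatinine, record.age, record.sex)
    comp = {
        "sbp_lt_100": 2 if record.sbp < 100 else 0,
        "syncope": 2 if record.syncope else 0,
        "hematemesis": 3 if record.hematemesis != Hematemesis.none else 0,
        "hb_lt_10": 1 if record.hemoglobin < 10 else 0,
        "bun_ge_22_4": 2 if bun_from_urea(record.urea) >= BUN_THRESHOLD else 0,
        "egfr_ge_60": -2 if egfr >= 60 else 0,
        "antiplatelet": -2 if record.antiplatelet else 0,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- INBS (ABC) ---------------------------------------------------------

INBS_AGE_BINS = ((60, 75, 1), (75, INF, 2))


def inbs(record: PatientRecord) -> ScoreResult:
    """International Bleeding Score (ABC), range 0-16.

    Laboratory thresholds are published in SI units and applied after
    conversion: urea > 10 mmol/L, albumin < 30 g/L, creatinine 100-150
    (1 point, upper bound inclusive) or > 150 umol/L (2 points).
    """
    name = "inbs"
    miss = _missing(
        record,
        ("age", "altered_mental_status", "comorbidities", "asa_class", "urea", "albumin", "creatinine"),
    )
    if miss:
        return _unusable(name, HIGHER_IS_WORSE, miss)
    creat_umol = creatinine_umol_from_mg(record.creatinine)
    if creat_umol > 150:
        creat_pts = 2
    elif creat_umol >= 100:
        creat_pts = 1
    else:
        creat_pts = 0
    comp = {
        "age": _bin(record.age, INBS_AGE_BINS),
        "altered_mental_status": 2 if record.altered_mental_status else 0,
        "liver_cirrhosis": 2
        if record.has_comorbidity("liver_disease_cirrhosis", "moderate_severe_liver_disease")
        else 0,
        "disseminated_malignancy": 2
        if record.has_comorbidity("disseminated_malignancy", "metastatic_solid_tumor")
        else 0,
        "asa": 3 if record.asa_class >= 4 else (1 if record.asa_class == 3 else 0),
        "urea_gt_10_mmol": 1 if urea_mmol_from_mg(record.urea) > 10 else 0,
        "albumin_lt_30_gl": 2 if record.albumin * 10 < 30 else 0,
        "creatinine": creat_pts,
    }
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- Charlson comorbidity index ----------------------------------------

#: Original 1987 weights over the 19 standard conditions.
CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "connective_tissue_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes": 1,
    "hemiplegia": 2,
    "moderate_severe_renal_disease": 2,
    "diabetes_with_end_organ_damage": 2,
    "any_tumor": 2,
    "leukemia": 2,
    "lymphoma": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids": 6,
}

#: Score-specific codes mapped onto their Charlson equivalents so the
#: same comorbidity never contributes twice.
_CHARLSON_ALIASES = {
    "cardiac_failure": "congestive_heart_failure",
    "ischemic_heart_disease": "myocardial_infarction",
    "renal_failure": "moderate_severe_renal_disease",
    "liver_disease_cirrhosis": "moderate_severe_liver_disease",
    "disseminated_malignancy": "metastatic_solid_tumor",
}


def charlson_index(record: PatientRecord) -> ScoreResult:
    """Charlson comorbidity index, original (non-age-adjusted) weights; 0-37."""
    name = "charlson_index"
    if record.comorbidities is None:
        return _unusable(name, HIGHER_IS_WORSE, ("comorbidities",))
    normalized = set()
    for code in record.comorbidities:
        canonical = _CHARLSON_ALIASES.get(code, code)
        if canonical not in CHARLSON_WEIGHTS:
            raise ValueError(f"unknown comorbidity code: {code!r}")
        normalized.add(canonical)
    comp = {code: CHARLSON_WEIGHTS[code] for code in sorted(normalized)}
    return ScoreResult(name, sum(comp.values()), HIGHER_IS_WORSE, comp)


# --- batch --------------------------------------------------------------

SCORE_FUNCTIONS: dict[str, Callable[[PatientRecord], ScoreResult]] = {
    "glasgow_blatchford": glasgow_blatchford,
    "modified_glasgow_blatchford": modified_glasgow_blatchford,
    "rockall_pre": rockall_pre,
    "baylor_pre": baylor_pre,
    "aim65": aim65,
    "t_score": t_score,
    "n_score": n_score,
    "modified_n_score": modified_n_score,
    "h3b2": h3b2,
    "map_score": map_score,
    "iino_score": iino_score,
    "inbs": inbs,
    "charlson_index": charlson_index,
}

#: Documented closed ranges (inclusive) for every score.
SCORE_RANGES = {
    "glasgow_blatchford": (0, 23),
    "modified_glasgow_blatchford": (0, 16),
    "rockall_pre": (0, 7),
    "baylor_pre": (0, 15),
    "aim65": (0, 5),
    "t_score": (4, 12),
    "n_score": (0, 7),
    "modified_n_score": (0, 7),
    "h3b2": (0, 6),
    "map_score": (0, 9),
    "iino_score": (-4, 10),
    "inbs": (0, 16),
    "charlson_index": (0, 37),
}


def score_all(record: PatientRecord) -> dict[str, ScoreResult]:
    """Compute every pre-endoscopic score; unusable ones are flagged."""
    return {name: fn(record) for name, fn in SCORE_FUNCTIONS.items()}
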