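"""Cirrhosis-severity scores: Child-Pugh-Turcotte, a creatinine-augmented
variant, and MELD.

These are evaluated on the cirrhosis subgroup of a bleeding cohort, where
liver failure rather than hemorrhage severity often drives mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .cohort import Ascites, Encephalopathy, PatientRecord

__all__ = ["LiverScoreResult", "child_pugh", "modified_child_pugh", "meld"]


@dataclass(frozen=True)
class LiverScoreResult:
    """A liver score: integer points with A/B/C class for CPT variants,
    a real value (plus nearest-integer rounding) for MELD."""

    name: str
    value: Optional[float]
    components: dict[str, float] = field(default_factory=dict)
    cpt_class: Optional[str] = None
    rounded: Optional[int] = None
    usable: bool = True
    missing: tuple[str, ...] = ()


def _missing(record: PatientRecord, fields: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(f for f in fields if getattr(record, f) is None)


def _cpt_class(points: int) -> str:
    if points <= 6:
        return "A"
    if points <= 9:
        return "B"
    return "C"


_CPT_FIELDS = ("bilirubin", "albumin", "inr", "ascites", "encephalopathy")


def _cpt_components(record: PatientRecord) -> dict[str, int]:
    bili = record.bilirubin
    alb = record.albumin
    inr = record.inr
    return {
        "bilirubin": 1 if bili < 2 else (2 if bili <= 3 else 3),
        "albumin": 1 if alb > 3.5 else (2 if alb >= 2.8 else 3),
        "inr": 1 if inr < 1.7 else (2 if inr <= 2.3 else 3),
        "ascites": {"none": 1, "mild": 2, "moderate_severe": 3}[record.ascites.value],
        "encephalopathy": {"none": 1, "grade_1_2": 2, "grade_3_4": 3}[
            record.encephalopathy.value
        ],
    }


def child_pugh(record: PatientRecord) -> LiverScoreResult:
    """Child-Pugh-Turcotte score: five 1-3 point items, total 5-15.

    Class A = 5-6, B = 7-9, C = 10-15.  Coagulation enters as INR.
    """
    miss = _missing(record, _CPT_FIELDS)
    if miss:
        return LiverScoreResult("child_pugh", None, usable=False, missing=miss)
    comp = _cpt_components(record)
    total = sum(comp.values())
    return LiverScoreResult(
        "child_pugh", total, comp, cpt_class=_cpt_class(total), rounded=total
    )


def modified_child_pugh(
    record: PatientRecord, creatinine_thresholds: tuple[float, float] = (1.3, 2.0)
) -> LiverScoreResult:
    """CPT augmented with a renal component, total 5-17.

    Creatinine (mg/dL) adds 0 points below the first threshold, 1 point
    between the thresholds, 2 points at or above the second (defaults
    1.3 and 2.0 mg/dL; configurable).  The A/B/C class is kept on the
    standard CPT boundaries of the unaugmented sum.
    """
    lo, hi = creatinine_thresholds
    if not lo < hi:
        raise ValueError(f"creatinine thresholds must be strictly increasing, got {creatinine_thresholds}")
    miss = _missing(record, _CPT_FIELDS + ("creatinine",))
    if miss:
        return LiverScoreResult("modified_child_pugh", None, usable=False, missing=miss)
    comp = _cpt_components(record)
    cr = record.creatinine
    comp["creatinine"] = 0 if cr < lo else (1 if cr < hi else 2)
    total = sum(comp.values())
    return LiverScoreResult(
        "modified_child_pugh",
        total,
        comp,
        cpt_class=_cpt_class(total - comp["creatinine"]),
        rounded=total,
    )


def meld(record: PatientRecord) -> LiverScoreResult:
    """Model for End-stage Liver Disease (UNOS convention).

    MELD = 9.57 ln(creatinine) + 3.78 ln(bilirubin) + 11.20 ln(INR) + 6.43
    with each laboratory value floored at 1.0 and creatinine capped at
    4.0 mg/dL.  Reported unrounded (``value``) and rounded to the nearest
    integer (``rounded``).
    """
    miss = _missing(record, ("bilirubin", "inr", "creatinine"))
    if miss:
        return LiverScoreResult("meld", None, usable=False, missing=miss)
    for name in ("bilirubin", "inr", "creatinine"):
        if getattr(record, name) <= 0:
            raise ValueError(f"{name} must be positive for MELD")
    cr = min(max(record.creatinine, 1.0), 4.0)
    bili = max(record.bilirubin, 1.0)
    inr = max(record.inr, 1.0)
    comp = {
        "creatinine_term": 9.57 * math.log(cr),
        "bilirubin_term": 3.78 * math.log(bili),
        "inr_term": 11.20 * math.log(inr),
        "constant": 6.43,
    }
    value = sum(comp.values())
    return LiverScoreResult("meld", value, comp, rounded=round(value))


LIVER_SCORE_FUNCTIONS = {
    "child_pugh": child_pugh,
    "modified_child_pugh": modified_child_pugh,
    "meld": meld,
}
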