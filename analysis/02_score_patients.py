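#!/usr/bin/env python
"""Score every patient in the simulated cohort.

Reads ``results/cohort.csv``, computes all thirteen pre-endoscopic
scores (plus CKD-EPI 2021 eGFR) per patient, and writes one row per
patient to ``results/patient_scores.csv``.  Prints the usable N per
score under the complete-case-per-score policy.
"""

from pathlib import Path

import pandas as pd

from ugib_scores.cohort import read_cohort
from ugib_scores.scores import SCORE_FUNCTIONS, score_all
from ugib_scores.units import egfr_ckd_epi_2021

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort.csv")
    rows = []
    for rec in cohort:
        row = {
            "id": rec.id,
            "etiology_group": rec.etiology_group.value,
            "outcome_death": int(rec.outcome_death),
        }
        for name, res in score_all(rec).items():
            row[name] = res.value
        if None not in (rec.creatinine, rec.age, rec.sex):
            row["egfr"] = round(egfr_ckd_epi_2021(rec.creatinine, rec.age, rec.sex), 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    out = ROOT / "patient_scores.csv"
    df.to_csv(out, index=False)
    print(f"scored {len(df)} patients -> {out}")
    print("usable N per score:")
    for name in SCORE_FUNCTIONS:
        print(f"  {name:<28} {df[name].notna().sum()}")


if __name__ == "__main__":
    main()
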