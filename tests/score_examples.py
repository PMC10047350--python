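"""Hand-summed golden examples for every score calculator.

Each entry is (score name, record field overrides, expected value).
Expected values were summed by hand from each score's published point
table; they double as the acceptance regression set.
"""

GOLDEN_EXAMPLES = [
    # Glasgow-Blatchford: 0-23
    ("glasgow_blatchford", {}, 0),
    (
        "glasgow_blatchford",
        dict(
            sex="male", urea=65.0, hemoglobin=11.0, sbp=95.0, heart_rate=110.0,
            melena=True, comorbidities=frozenset({"liver_disease_cirrhosis"}),
        ),
        13,  # 4 + 3 + 2 + 1 + 1 + 2
    ),
    (
        "glasgow_blatchford",
        dict(
            sex="male", urea=180.0, hemoglobin=9.0, sbp=80.0, heart_rate=120.0,
            melena=True, syncope=True,
            comorbidities=frozenset({"liver_disease_cirrhosis", "cardiac_failure"}),
        ),
        23,  # 6 + 6 + 3 + 1 + 1 + 2 + 2 + 2
    ),
    # modified GBS: 0-16 (urea + Hb + sBP + pulse only)
    ("modified_glasgow_blatchford", {}, 0),
    (
        "modified_glasgow_blatchford",
        dict(sex="male", urea=65.0, hemoglobin=11.0, sbp=95.0, heart_rate=110.0),
        10,
    ),
    (
        "modified_glasgow_blatchford",
        dict(sex="female", urea=150.0, hemoglobin=9.9, sbp=89.0, heart_rate=101.0),
        16,
    ),
    # pre-endoscopic Rockall: 0-7
    ("rockall_pre", dict(age=45, heart_rate=80.0, sbp=130.0), 0),
    (
        "rockall_pre",
        dict(age=70, heart_rate=105.0, sbp=110.0,
             comorbidities=frozenset({"cardiac_failure"})),
        4,  # 1 + 1 + 2
    ),
    (
        "rockall_pre",
        dict(age=82, heart_rate=80.0, sbp=85.0,
             comorbidities=frozenset({"disseminated_malignancy"})),
        7,  # 2 + 2 + 3
    ),
    # pre-endoscopic Baylor: 0-15
    ("baylor_pre", dict(age=25, comorbidity_count=0, comorbidity_severity="none"), 0),
    ("baylor_pre", dict(age=65, comorbidity_count=3, comorbidity_severity="chronic"), 11),
    ("baylor_pre", dict(age=75, comorbidity_count=6, comorbidity_severity="acute"), 15),
    # AIM65: 0-5
    ("aim65", dict(age=50, sbp=120.0, albumin=3.8, inr=1.0), 0),
    ("aim65", dict(age=70, albumin=2.5), 2),
    (
        "aim65",
        dict(age=70, sbp=85.0, altered_mental_status=True, albumin=2.5, inr=1.8),
        5,
    ),
    # T-score: 4-12, lower is worse
    ("t_score", dict(heart_rate=120.0, sbp=85.0, hemoglobin=7.0, general_condition="poor"), 4),
    ("t_score", dict(heart_rate=70.0, sbp=130.0, hemoglobin=12.0, general_condition="good"), 12),
    ("t_score", dict(heart_rate=95.0, sbp=100.0, hemoglobin=9.5, general_condition="intermediate"), 8),
    # N-score: 0-7
    ("n_score", dict(urea=30.0, creatinine=1.0), 0),
    ("n_score", dict(hematemesis="red_blood", urea=54.0, creatinine=1.0), 3),  # 2 + 1
    (
        "n_score",
        dict(syncope=True, hematemesis="red_blood", urea=65.0, creatinine=0.8),
        7,  # 3 + 2 + 1 + 1
    ),
    # modified N-score grades hematemesis type
    ("modified_n_score", dict(hematemesis="coffee_ground", urea=30.0, creatinine=1.0), 1),
    ("modified_n_score", dict(hematemesis="red_blood", urea=30.0, creatinine=1.0), 2),
    ("modified_n_score", dict(syncope=True, hematemesis="coffee_ground", urea=30.0, creatinine=1.0), 4),
    # H3B2: 0-6
    ("h3b2", {}, 0),
    ("h3b2", dict(hematemesis="red_blood", hemoglobin=9.0, urea=65.0), 4),  # 1 + 1 + 2
    (
        "h3b2",
        dict(hematemesis="coffee_ground", heart_rate=100.0, sbp=100.0, hemoglobin=10.0, urea=65.0),
        6,
    ),
    # MAP (ASH): 0-9
    ("map_score", dict(asa_class=1), 0),
    ("map_score", dict(asa_class=3, hemoglobin=9.0), 3),  # 1 + 2
    (
        "map_score",
        dict(altered_mental_status=True, asa_class=4, heart_rate=110.0,
             sbp=85.0, hemoglobin=9.0, albumin=2.0),
        9,
    ),
    # Iino: -4..10
    ("iino_score", dict(antiplatelet=True), -4),  # eGFR >= 60 (-2) + antiplatelet (-2)
    (
        "iino_score",
        dict(hematemesis="red_blood", urea=54.0, creatinine=1.0, age=60),
        3,  # 3 + 2 - 2 (eGFR ~86 >= 60)
    ),
    (
        "iino_score",
        dict(sbp=90.0, syncope=True, hematemesis="red_blood", hemoglobin=9.0,
             urea=65.0, creatinine=1.8, age=70),
        10,  # 2 + 2 + 3 + 1 + 2, eGFR ~40 < 60
    ),
    # INBS (ABC): 0-16
    ("inbs", dict(age=40, asa_class=1), 0),
    (
        "inbs",
        dict(age=68, comorbidities=frozenset({"liver_disease_cirrhosis"}),
             urea=72.1, albumin=2.8, creatinine=1.36),
        7,  # 1 + 2 + 1 + 2 + 1; the published mortality cutoff
    ),
    (
        "inbs",
        dict(age=80, altered_mental_status=True,
             comorbidities=frozenset({"liver_disease_cirrhosis", "disseminated_malignancy"}),
             asa_class=4, urea=80.0, albumin=2.5, creatinine=1.81),
        16,  # 2 + 2 + 2 + 2 + 3 + 1 + 2 + 2
    ),
    # Charlson comorbidity index: 0-37
    ("charlson_index", {}, 0),
    (
        "charlson_index",
        dict(comorbidities=frozenset(
            {"congestive_heart_failure", "diabetes", "metastatic_solid_tumor"})),
        8,  # 1 + 1 + 6
    ),
    ("charlson_index", dict(comorbidities=frozenset({"moderate_severe_liver_disease"})), 3),
]
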