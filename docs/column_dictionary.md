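# Cohort CSV column dictionary

Comma-separated, UTF-8, dot decimal. Booleans are `1`/`0` (also accepted:
`true`/`false`, `yes`/`no`). Enumerations are lowercase `snake_case`.
An empty cell means the value is missing, except `comorbidities`, where it
means "no comorbidities recorded". Every column must be present in the
header; `id` and `outcome_death` must be non-empty in every row.

| column | type / unit | values |
|---|---|---|
| `id` | string | unique patient identifier |
| `age` | integer, years | >= 16 |
| `sex` | enum | `male`, `female` |
| `sbp` | float, mmHg | systolic blood pressure, > 0 |
| `heart_rate` | float, beats/min | > 0 |
| `hemoglobin` | float, g/dL | > 0 |
| `urea` | float, mg/dL | > 0 (BUN and mmol/L are derived, never stored) |
| `creatinine` | float, mg/dL | > 0 |
| `albumin` | float, g/dL | > 0 |
| `inr` | float, ratio | > 0 |
| `bilirubin` | float, mg/dL | > 0; required only by liver scores |
| `syncope` | bool | |
| `melena` | bool | |
| `hematochezia` | bool | |
| `hematemesis` | enum | `none`, `coffee_ground`, `red_blood` |
| `altered_mental_status` | bool | |
| `general_condition` | enum | `poor`, `intermediate`, `good` |
| `asa_class` | integer | 1..5 |
| `antiplatelet` | bool | |
| `anticoagulant` | bool | |
| `nsaid` | bool | |
| `comorbidities` | `;`-separated codes | Charlson-1987 condition codes plus `cardiac_failure`, `ischemic_heart_disease`, `renal_failure`, `liver_disease_cirrhosis`, `disseminated_malignancy` |
| `comorbidity_count` | integer | number of distinct diseases (Baylor input) |
| `comorbidity_severity` | enum | `none`, `chronic`, `acute` (Baylor input) |
| `ascites` | enum | `none`, `mild`, `moderate_severe` |
| `encephalopathy` | enum | `none`, `grade_1_2`, `grade_3_4` |
| `covid_status` | enum | `positive`, `negative`, `untested`, `prepandemic` |
| `period` | enum | `prepandemic`, `pandemic` (prepandemic forces `covid_status = prepandemic`) |
| `etiology_group` | enum | `nonvariceal`, `variceal`, `no_endoscopy` |
| `outcome_death` | bool | in-hospital death |

Charlson condition codes: `myocardial_infarction`, `congestive_heart_failure`,
`peripheral_vascular_disease`, `cerebrovascular_disease`, `dementia`,
`chronic_pulmonary_disease`, `connective_tissue_disease`,
`peptic_ulcer_disease`, `mild_liver_disease`, `diabetes`, `hemiplegia`,
`moderate_severe_renal_disease`, `diabetes_with_end_organ_damage`,
`any_tumor`, `leukemia`, `lymphoma`, `moderate_severe_liver_disease`,
`metastatic_solid_tumor`, `aids`.
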