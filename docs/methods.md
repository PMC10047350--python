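# Methods

## Problem and scope

In upper gastrointestinal bleeding (UGIB), a minority of patients never
undergo endoscopy — because they refuse, are too unstable, or die first —
and their in-hospital mortality is substantially higher than in either
variceal or non-variceal bleeding with a confirmed source. For this group
only *pre-endoscopic* risk scores are computable. The package implements
thirteen such scores plus three cirrhosis-severity scores, the
discrimination and association analytics used to compare them, and a
synthetic cohort generator that reproduces the statistical structure of a
three-group UGIB population so the whole pipeline can be exercised and
tested without patient-level data.

## Score calculators

All scores are pure functions of a validated `PatientRecord` and return a
per-component breakdown whose sum is the score value.

* **Glasgow-Blatchford (0-23)** and **modified GBS (0-16)** — the modified
  form drops melena, syncope, and comorbidity items, keeping urea,
  hemoglobin, systolic pressure and pulse.
* **Pre-endoscopic Rockall (0-7)** — age, shock tier, comorbidity tier;
  comorbidity points are non-additive (the worst applicable tier counts).
* **Pre-endoscopic Baylor (0-15)** — age, number of diseases, disease
  severity; acute dominates chronic.
* **AIM65 (0-5)** — albumin < 3 g/dL, INR > 1.5, altered mental status,
  age > 65, systolic BP < 90 mmHg.
* **T-score (4-12)** — the only lower-is-worse score (best clinical state
  scores 12). Its printed hemoglobin bands (<= 8 / 9-10 / > 10) leave
  (8, 9) uncovered; the middle band is read as (8, 10] for contiguity.
* **N-score / modified N-score (0-7)** — syncope 3, hematemesis 2,
  BUN >= 22.4 mg/dL 1, BUN/creatinine >= 30 1; the modified form grades
  hematemesis (red blood 2, coffee-ground 1), so it is never larger than
  the original and equal whenever hematemesis is absent or red.
* **H3B2 (0-6)**, **MAP/ASH (0-9)**, **Iino (-4..10)**, **INBS/ABC
  (0-16)** — per their point tables; Iino's renal item uses the race-free
  CKD-EPI 2021 eGFR, and its two protective items (preserved eGFR,
  antiplatelet use) make the range extend below zero.
* **Charlson comorbidity index (0-37)** — original 1987 weights, not
  age-adjusted (age already enters most bleeding scores). Score-specific
  codes (e.g. `cardiac_failure`) are normalized onto their Charlson
  equivalents before summing so a disease never counts twice.

Units are canonical (urea, creatinine, bilirubin mg/dL; albumin g/dL);
thresholds published in SI units (INBS: urea > 10 mmol/L, albumin
< 30 g/L, creatinine 100-150 / > 150 umol/L) are applied after exact
molar-mass conversion. BUN is always derived from urea
(x 28.01/60.06), never a separate input, which keeps the 22.4 mg/dL BUN
threshold consistent with the GBS 48 mg/dL urea bin edge.

Printed integer bins are half-open on the right ([39, 48), [48, 60),
[60, 150), >= 150 for GBS urea), resolving the overlapping printed ranges
and matching the original SI-unit bin edges; the INBS creatinine
"100-150" band includes 150.

**Missing data.** Complete case per score: a score is computed only when
all of its own inputs are present; otherwise the result is flagged
unusable with the missing fields named, never silently zeroed, and every
report carries the per-score usable N.

**Liver scores.** Child-Pugh-Turcotte uses INR for coagulation (the
cohort field collected); class A/B/C at 5-6/7-9/>= 10. MELD follows the
UNOS convention — 9.57 ln(creatinine) + 3.78 ln(bilirubin) +
11.20 ln(INR) + 6.43 with labs floored at 1.0 and creatinine capped at
4.0 — reported unrounded and rounded. The creatinine-augmented CPT is not
fully specified in the literature this package follows; the rule here
(0/1/2 points below 1.3 / in [1.3, 2.0) / at or above 2.0 mg/dL,
configurable) is an explicit package choice.

## Evaluation analytics

* **AUC** — midrank (Mann-Whitney) estimator; lower-is-worse scores are
  sign-flipped first, so `auc` is always "probability a death outranks a
  survivor toward risk", ties half.
* **AUC confidence intervals** — DeLong structural-component variance
  with a normal interval truncated to [0, 1] (deterministic; the method
  of choice when the source of a printed CI is unstated). A stratified
  bootstrap percentile CI is provided as a cross-check and agrees with
  DeLong to well under 0.02 at n = 200.
  Zero-variance data (perfect separation) yields the degenerate point
  interval rather than NaN.
* **Cutoffs** — Youden's J maximized over the distinct observed score
  values; ties broken toward the most sensitive threshold; infinite
  sentinels are not eligible cutoffs, so degenerate data returns J = 0 at
  the smallest observed value.
* **Odds ratios** — (a d)/(b c) with Woolf logit CIs
  exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)) and a Wald z test on the
  log OR (this is the p-value that accompanies published ORs of this
  form; Pearson chi-square gives different values). Zero cells use the
  Haldane-Anscombe +0.5 on all four cells, applied only when a zero
  exists and flagged in output.
* **Group comparisons** — Pearson chi-square (optional Yates), Fisher
  exact (two-sided by enumeration), Mann-Whitney with exact small-sample
  p and tie-corrected normal approximation otherwise (via scipy).
* **Swets bands** — AUC 0.5 non-informative, (0.5, 0.7) less accurate,
  [0.7, 0.9) moderately accurate, [0.9, 1) highly accurate, 1 perfect;
  boundaries are assigned upward (exactly 0.7 is "moderate"), a
  convention that matters only for values sitting exactly on a boundary.

## Synthetic cohort generator

The generator emulates a 2455-admission UGIB population in three etiology
groups (non-variceal 66.3%, variceal 21.2%, no endoscopy 8.1%,
renormalized) with target in-hospital mortality 7.4% / 21.9% / 37.9%.

Mechanism — a single latent severity factor `S ~ N(0, 1)` per patient:

* **Labs** are log-normal around group means (no-endoscopy: hemoglobin
  8.39 g/dL, urea 90.7 mg/dL, creatinine 1.56 mg/dL, albumin 2.82 g/dL,
  INR 1.77; the other groups use their published means) with a
  per-covariate severity loading on the log scale; the mean is preserved
  exactly. Dispersions are fixed package defaults of roughly 20-50%
  coefficient of variation by analyte (only means are published).
* **Vitals** (age, systolic BP, heart rate) are normal with additive
  loadings; blood pressure, heart rate and bilirubin means are typical
  UGIB-admission values, as they are not published per group.
* **Binary and ordered fields** (syncope, melena, hematemesis type,
  altered mental status, general condition, ASA class, comorbidity
  presence, COVID positivity) use logistic / ordered-logistic links to
  `S` with base rates anchored to the published group percentages where
  available.
* **Death** is Bernoulli(expit(alpha_group + beta·S)). For any beta, each
  group intercept is recalibrated by bisection against Gauss-Hermite
  quadrature of E[expit(alpha + beta·S)], so realized group mortality
  matches its target in expectation regardless of the link strength.
* Identical config (including seed) gives a byte-identical cohort.

Because every score is built from severity-loaded covariates, all of them
discriminate death; their relative ordering *emerges* from the covariate
structure rather than being forced per score. `calibrate_auc_band`
adjusts only the single death-link `beta` (bisection on a large generated
cohort) until a named score's AUC enters a target band.

The default `beta = 2.8` was fixed at design time so that the
default-configuration AUCs on a large no-endoscopy cohort fall inside the
published per-score confidence ranges for INBS (~0.82), GBS, MAP,
N-score, Baylor and the Charlson index. Known departures from the real
cohort: the generated T-score discriminates well (flipped AUC ~0.8)
where the study found it weak (0.563) — a single-factor severity model
cannot make one clinically loaded score uninformative while its
components drive other scores; the modified GBS is nearly as strong as
the full GBS; and the generator draws comorbidities independently given
severity, so comorbidity clustering is not reproduced. Passing the
generator-based checks therefore demonstrates pipeline correctness and
realistic orderings, not the study's exact AUC point values, which
require the original patient-level data.

`missingness_rate` (default 0) masks each optional clinical field
independently; the study's incomplete records (only 122 of 198 patients
scorable on every system) can be emulated with rates around 0.05-0.1.
The default keeps cohorts complete so discrimination checks are not
confounded with missingness.

## Published-count contrasts

Five odds-ratio contrasts are fully determined by printed counts and are
embedded as data (deaths/survivors: no-endoscopy 75/123, variceal
114/406, non-variceal 121/1507; no-endoscopy pre-pandemic 36/76 vs
pandemic 39/47; COVID-positive 18/5 vs negative 11/25; pandemic excluding
positives 21/42). `reproduce_printed_contingency_analyses` recomputes OR,
Woolf CI and Wald p for each, plus the 75/198 = 37.9% mortality rate.
The recomputed Woolf bounds match the published ones to ~1e-3 (one
published interval, 1.5235-3.0953, differs from exact Woolf recomputation
by 3e-4 — consistent with rounding in the source's software). A
post-mortem pathology contrast published without a reconstructible 2x2 is
deliberately not included.

## Problem sizes and numerical choices

Generator-based checks use n = 20000 (group mortality within ±0.02 of
target; binomial SE ≈ 0.012 for the smallest group) and n = 4000 for
quick property tests; the AUC engine is verified against brute-force pair
counting on 1000 random instances of n ≤ 50 and against a 2000-replicate
bootstrap at n = 200. Intercept calibration bisects to ~1e-10 on a
64-node Gauss-Hermite grid; AUC band calibration bisects beta over
[0.05, 8] and reports the achievable range when a band is unreachable.
Generated values are rounded to measurement-realistic precision (vitals
integer; labs 1-2 decimals), which also makes CSV round-trips exact.

## Limitations

* Endoscopic score components (full Rockall/Baylor), CSMCPI, PNED and
  Harbinger scores are out of scope; the cohort modelled has no
  endoscopy-derived fields.
* The generator targets means, rates and AUC bands — not higher moments,
  covariate correlations beyond the single factor, or the study's exact
  score distributions (its published mean-score table is checked only
  directionally).
* MELD-Na and other MELD revisions are not implemented.
* Thirty-day / post-discharge mortality is not modelled; the outcome is
  in-hospital death only.
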