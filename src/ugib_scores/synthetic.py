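"""Synthetic upper-GI-bleeding cohort generator.

Emulates the statistical structure of a three-group bleeding cohort
(non-variceal, variceal, and "no endoscopy performed / unknown
etiology") so the whole scoring-and-evaluation pipeline can be
exercised without patient-level data.

Mechanism: each patient carries a latent severity ``S ~ N(0, 1)``.
Group-specific covariate means (anchored to the published descriptive
table: e.g. no-endoscopy hemoglobin 8.39 g/dL, urea 90.7 mg/dL,
creatinine 1.56 mg/dL, albumin 2.82 g/dL, INR 1.77) are shifted by a
per-covariate severity loading; laboratory values are log-normal (kept
positive), vitals normal, and binary or ordered categorical fields use
logistic links to ``S``.  Death is Bernoulli(expit(alpha_group +
beta * S)) with ``alpha_group`` calibrated by bisection against the
target group mortality (defaults 7.4% / 21.9% / 37.9%), so realized
mortality matches its target in expectation for any ``beta``.

Because every score is built from severity-loaded covariates, all of
them discriminate death (AUC > 0.5); :func:`calibrate_auc_band` rescales
only the death link ``beta`` until a named score's AUC lands in a target
band, so inter-score AUC ordering emerges from the covariate structure
rather than being forced per score.

Identical config (including seed) always yields a byte-identical cohort.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, logit

from .cohort import Cohort, PatientRecord, config_digest
from .evaluation import auc
from .scores import SCORE_FUNCTIONS

__all__ = [
    "SyntheticCohortConfig",
    "generate_cohort",
    "calibrate_auc_band",
    "CalibrationError",
    "GROUPS",
]

GROUPS = ("nonvariceal", "variceal", "no_endoscopy")

#: Group shares of the study population (non-variceal 66.3%, variceal
#: 21.2%, no endoscopy 8.1%; renormalized over the three modelled groups).
DEFAULT_GROUP_MIX = {"nonvariceal": 0.663, "variceal": 0.212, "no_endoscopy": 0.081}

#: Target in-hospital mortality per group.
DEFAULT_GROUP_MORTALITY = {
    "nonvariceal": 0.074,
    "variceal": 0.219,
    "no_endoscopy": 0.379,
}

#: Published group means; blood pressure, heart rate and bilirubin are
#: not tabulated in the source cohort and use typical UGIB-admission values.
DEFAULT_COVARIATE_MEANS = {
    "nonvariceal": {
        "age": 63.9, "sbp": 115.0, "heart_rate": 92.0, "hemoglobin": 8.77,
        "urea": 82.6, "creatinine": 1.24, "albumin": 3.27, "inr": 1.58,
        "bilirubin": 1.2,
    },
    "variceal": {
        "age": 58.7, "sbp": 112.0, "heart_rate": 95.0, "hemoglobin": 8.28,
        "urea": 65.1, "creatinine": 0.96, "albumin": 2.70, "inr": 1.74,
        "bilirubin": 3.0,
    },
    "no_endoscopy": {
        "age": 65.0, "sbp": 112.0, "heart_rate": 95.0, "hemoglobin": 8.39,
        "urea": 90.7, "creatinine": 1.56, "albumin": 2.82, "inr": 1.77,
        "bilirubin": 2.0,
    },
}

# (severity loading, residual sd) on the log scale for labs,
# additive for vitals.  Labs keep E[X] = group mean exactly.
_LAB_PARAMS = {
    "hemoglobin": (-0.11, 0.16),
    "urea": (0.45, 0.40),
    "creatinine": (0.32, 0.32),
    "albumin": (-0.09, 0.10),
    "inr": (0.16, 0.16),
    "bilirubin": (0.40, 0.55),
}
_VITAL_PARAMS = {
    "age": (4.0, 15.0, 16, 100),
    "sbp": (-12.0, 16.0, 50, 220),
    "heart_rate": (10.0, 14.0, 40, 190),
}
_LAB_CLIPS = {
    "hemoglobin": (2.5, 18.0),
    "urea": (5.0, 500.0),
    "creatinine": (0.2, 15.0),
    "albumin": (1.2, 5.5),
    "inr": (0.8, 12.0),
    "bilirubin": (0.2, 40.0),
}

# binary flags: (base rate per group, severity loading)
_FLAG_PARAMS = {
    "syncope": ({"nonvariceal": 0.15, "variceal": 0.15, "no_endoscopy": 0.17}, 0.8),
    "melena": ({"nonvariceal": 0.869, "variceal": 0.896, "no_endoscopy": 0.813}, 0.3),
    "hematochezia": ({"nonvariceal": 0.026, "variceal": 0.05, "no_endoscopy": 0.101}, 0.2),
    "altered_mental_status": ({"nonvariceal": 0.10, "variceal": 0.13, "no_endoscopy": 0.16}, 1.2),
    "antiplatelet": ({"nonvariceal": 0.065, "variceal": 0.006, "no_endoscopy": 0.03}, 0.0),
    "anticoagulant": ({"nonvariceal": 0.133, "variceal": 0.017, "no_endoscopy": 0.04}, 0.0),
    "nsaid": ({"nonvariceal": 0.154, "variceal": 0.031, "no_endoscopy": 0.04}, 0.0),
}

# comorbidity components: code(s), base rate per group, loading
_COMORBIDITY_PARAMS = [
    ("liver_disease_cirrhosis", {"nonvariceal": 0.11, "variceal": 0.967, "no_endoscopy": 0.359}, 0.4),
    ("renal_failure", {"nonvariceal": 0.077, "variceal": 0.015, "no_endoscopy": 0.071}, 0.5),
    ("cardiac_failure", {"nonvariceal": 0.075, "variceal": 0.017, "no_endoscopy": 0.063}, 0.5),
    ("ischemic_heart_disease", {"nonvariceal": 0.075, "variceal": 0.017, "no_endoscopy": 0.063}, 0.4),
    ("disseminated_malignancy", {"nonvariceal": 0.004, "variceal": 0.006, "no_endoscopy": 0.046}, 0.6),
    ("diabetes", {"nonvariceal": 0.18, "variceal": 0.18, "no_endoscopy": 0.18}, 0.2),
    ("chronic_pulmonary_disease", {"nonvariceal": 0.10, "variceal": 0.10, "no_endoscopy": 0.12}, 0.3),
    ("cerebrovascular_disease", {"nonvariceal": 0.08, "variceal": 0.05, "no_endoscopy": 0.12}, 0.5),
    ("dementia", {"nonvariceal": 0.04, "variceal": 0.03, "no_endoscopy": 0.08}, 0.4),
    ("any_tumor", {"nonvariceal": 0.05, "variceal": 0.04, "no_endoscopy": 0.05}, 0.3),
    ("peptic_ulcer_disease", {"nonvariceal": 0.12, "variceal": 0.05, "no_endoscopy": 0.08}, 0.1),
]

# ordered categoricals: levels worst-last, base marginal probs, loading
_GENERAL_CONDITION = (("good", "intermediate", "poor"), (0.30, 0.45, 0.25), 1.5)
_ASA = ((1, 2, 3, 4, 5), (0.08, 0.27, 0.40, 0.20, 0.05), 1.2)
_ASCITES = (("none", "mild", "moderate_severe"), (0.45, 0.30, 0.25), 1.0)
_ENCEPHALOPATHY = (("none", "grade_1_2", "grade_3_4"), (0.70, 0.20, 0.10), 1.2)

_PANDEMIC_SHARE = 0.43          # admissions in the pandemic window
_COVID_POSITIVE_BASE = 0.20     # among pandemic admissions, at S = 0
_COVID_POSITIVE_LOADING = 0.8   # infection associates with severity/death
_UNTESTED_SHARE = 0.40          # among pandemic non-positives

#: Optional clinical fields subject to missingness masking.
_MASKABLE_FIELDS = [
    "sbp", "heart_rate", "hemoglobin", "urea", "creatinine", "albumin",
    "inr", "bilirubin", "syncope", "melena", "hematochezia", "hematemesis",
    "altered_mental_status", "general_condition", "asa_class",
    "antiplatelet", "anticoagulant", "nsaid", "comorbidity_severity",
]


class SyntheticCohortConfig(BaseModel):
    """Generator configuration; defaults reproduce the study conditions."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=2455, ge=1)
    group_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_GROUP_MIX))
    group_mortality: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_MORTALITY)
    )
    covariate_means: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATE_MEANS.items()}
    )
    severity_beta: float = Field(default=2.8, ge=0.0)
    missingness_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_groups(self):
        for name, d in (("group_mix", self.group_mix), ("group_mortality", self.group_mortality)):
            if set(d) != set(GROUPS):
                raise ValueError(f"{name} must have exactly the keys {GROUPS}")
        if any(v < 0 for v in self.group_mix.values()) or sum(self.group_mix.values()) <= 0:
            raise ValueError("group_mix proportions must be non-negative with positive sum")
        for g, p in self.group_mortality.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"group_mortality[{g!r}] = {p} not in (0, 1): calibration infeasible"
                )
        return self

    def mix_probabilities(self) -> np.ndarray:
        raw = np.array([self.group_mix[g] for g in GROUPS], dtype=float)
        return raw / raw.sum()

    def digest(self) -> str:
        return config_digest(json.dumps(self.model_dump(), sort_keys=True))


class CalibrationError(RuntimeError):
    pass


# Gauss-Hermite nodes for E over S ~ N(0,1)
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(64)
_GH_S = np.sqrt(2.0) * _GH_X
_GH_P = _GH_W / np.sqrt(np.pi)


def _calibrate_alpha(target: float, beta: float) -> float:
    """Solve E_{S~N(0,1)}[expit(alpha + beta S)] = target by bisection."""

    def realized(alpha: float) -> float:
        return float(np.sum(_GH_P * expit(alpha + beta * _GH_S)))

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ordered_draw(rng, levels, base_probs, loading, severity):
    """Ordered-logistic draw: latent = loading*S + logistic noise against
    cutpoints fixed by the base marginal distribution."""
    cum = np.cumsum(base_probs)[:-1]
    cutpoints = logit(cum)
    latent = loading * severity + rng.logistic(size=len(severity))
    idx = np.searchsorted(cutpoints, latent)
    return np.asarray(levels, dtype=object)[idx]


def _flag_draw(rng, base, loading, severity):
    return rng.random(len(severity)) < expit(logit(base) + loading * severity)


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a validated synthetic cohort (deterministic in the config)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    mix = config.mix_probabilities()
    group_idx = rng.choice(len(GROUPS), size=n, p=mix)
    group = np.asarray(GROUPS, dtype=object)[group_idx]
    severity = rng.standard_normal(n)
    beta = config.severity_beta

    alphas = {g: _calibrate_alpha(config.group_mortality[g], beta) for g in GROUPS}
    alpha_vec = np.array([alphas[g] for g in group])
    death = rng.random(n) < expit(alpha_vec + beta * severity)

    male_share = np.array(
        [{"nonvariceal": 0.676, "variceal": 0.658, "no_endoscopy": 0.601}[g] for g in group]
    )
    is_male = rng.random(n) < male_share

    def group_means(cov: str) -> np.ndarray:
        return np.array([config.covariate_means[g][cov] for g in group])

    values: dict[str, np.ndarray] = {}
    for cov, (lam, sd, lo, hi) in _VITAL_PARAMS.items():
        x = group_means(cov) + lam * severity + sd * rng.standard_normal(n)
        values[cov] = np.clip(np.round(x), lo, hi)
    for cov, (lam, sd) in _LAB_PARAMS.items():
        shift = lam * severity + sd * rng.standard_normal(n) - 0.5 * (lam**2 + sd**2)
        x = group_means(cov) * np.exp(shift)
        lo, hi = _LAB_CLIPS[cov]
        digits = 1 if cov == "urea" else 2
        values[cov] = np.round(np.clip(x, lo, hi), digits)

    flags: dict[str, np.ndarray] = {}
    for name, (base, lam) in _FLAG_PARAMS.items():
        base_vec = np.array([base[g] for g in group])
        flags[name] = _flag_draw(rng, base_vec, lam, severity)

    hema_base = np.array(
        [{"nonvariceal": 0.458, "variceal": 0.787, "no_endoscopy": 0.50}[g] for g in group]
    )
    hema_any = _flag_draw(rng, hema_base, 0.6, severity)
    hema_red = _flag_draw(rng, 0.5 * np.ones(n), 0.5, severity)
    hematemesis = np.where(hema_any, np.where(hema_red, "red_blood", "coffee_ground"), "none")

    comorbidities: list[set[str]] = [set() for _ in range(n)]
    for code, base, lam in _COMORBIDITY_PARAMS:
        base_vec = np.array([base[g] for g in group])
        present = _flag_draw(rng, base_vec, lam, severity)
        for i in np.flatnonzero(present):
            comorbidities[i].add(code)
    cirrhosis = np.array(["liver_disease_cirrhosis" in c for c in comorbidities])
    count = np.array([len(c) for c in comorbidities])

    condition = _ordered_draw(rng, *_GENERAL_CONDITION, severity=severity)
    asa = _ordered_draw(rng, *_ASA, severity=severity)
    acute = _flag_draw(rng, 0.33 * np.ones(n), 0.8, severity)
    severity_cat = np.where(count == 0, "none", np.where(acute, "acute", "chronic"))
    ascites = _ordered_draw(rng, *_ASCITES, severity=severity)
    ascites = np.where(cirrhosis, ascites, "none")
    enceph = _ordered_draw(rng, *_ENCEPHALOPATHY, severity=severity)
    enceph = np.where(cirrhosis, enceph, "none")

    pandemic = rng.random(n) < _PANDEMIC_SHARE
    covid_pos = _flag_draw(
        rng, _COVID_POSITIVE_BASE * np.ones(n), _COVID_POSITIVE_LOADING, severity
    )
    untested = rng.random(n) < _UNTESTED_SHARE
    covid = np.where(
        ~pandemic,
        "prepandemic",
        np.where(covid_pos, "positive", np.where(untested, "untested", "negative")),
    )

    if config.missingness_rate > 0:
        mask = rng.random((n, len(_MASKABLE_FIELDS))) < config.missingness_rate
    else:
        mask = np.zeros((n, len(_MASKABLE_FIELDS)), dtype=bool)
    masked = {f: mask[:, j] for j, f in enumerate(_MASKABLE_FIELDS)}

    width = len(str(n))
    records = []
    for i in range(n):
        data = {
            "id": f"P{i + 1:0{width}d}",
            "age": int(values["age"][i]),
            "sex": "male" if is_male[i] else "female",
            "sbp": float(values["sbp"][i]),
            "heart_rate": float(values["heart_rate"][i]),
            "hemoglobin": float(values["hemoglobin"][i]),
            "urea": float(values["urea"][i]),
            "creatinine": float(values["creatinine"][i]),
            "albumin": float(values["albumin"][i]),
            "inr": float(values["inr"][i]),
            "bilirubin": float(values["bilirubin"][i]),
            "syncope": bool(flags["syncope"][i]),
            "melena": bool(flags["melena"][i]),
            "hematochezia": bool(flags["hematochezia"][i]),
            "hematemesis": str(hematemesis[i]),
            "altered_mental_status": bool(flags["altered_mental_status"][i]),
            "general_condition": str(condition[i]),
            "asa_class": int(asa[i]),
            "antiplatelet": bool(flags["antiplatelet"][i]),
            "anticoagulant": bool(flags["anticoagulant"][i]),
            "nsaid": bool(flags["nsaid"][i]),
            "comorbidities": frozenset(comorbidities[i]),
            "comorbidity_count": int(count[i]),
            "comorbidity_severity": str(severity_cat[i]),
            "ascites": str(ascites[i]),
            "encephalopathy": str(enceph[i]),
            "covid_status": str(covid[i]),
            "period": "pandemic" if pandemic[i] else "prepandemic",
            "etiology_group": str(group[i]),
            "outcome_death": bool(death[i]),
        }
        for f in _MASKABLE_FIELDS:
            if masked[f][i]:
                data[f] = None
        records.append(PatientRecord(**data))
    return Cohort(records=tuple(records), provenance=f"synthetic:{config.digest()}")


def _score_auc(cohort: Cohort, score_name: str) -> float:
    fn = SCORE_FUNCTIONS[score_name]
    vals, labels, direction = [], [], None
    for rec in cohort:
        res = fn(rec)
        direction = res.direction
        if res.usable:
            vals.append(res.value)
            labels.append(rec.outcome_death)
    return auc(vals, labels, direction)


def calibrate_auc_band(
    config: SyntheticCohortConfig,
    score_name: str,
    target_band: tuple[float, float],
    n_eval: int = 20000,
    beta_bounds: tuple[float, float] = (0.05, 8.0),
    max_iter: int = 25,
) -> tuple[SyntheticCohortConfig, float]:
    """Rescale the severity-to-death link until ``score_name``'s AUC on a
    large generated cohort falls inside ``target_band``.

    Only ``severity_beta`` is adjusted (group mortality stays on target
    because the intercepts are recalibrated at every beta).  Returns the
    adjusted config and the achieved AUC; raises :class:`CalibrationError`
    with the achievable AUC range when the band cannot be reached.
    """
    if score_name not in SCORE_FUNCTIONS:
        raise KeyError(f"unknown score {score_name!r}")
    lo_t, hi_t = target_band
    if not lo_t < hi_t:
        raise ValueError("target band must be (lo, hi) with lo < hi")

    def achieved(beta: float) -> float:
        cfg = config.model_copy(update={"severity_beta": beta, "n": n_eval})
        return _score_auc(generate_cohort(cfg), score_name)

    beta = config.severity_beta
    a = achieved(beta)
    if lo_t <= a <= hi_t:
        return config, a

    b_lo, b_hi = beta_bounds
    # AUC is monotone increasing in beta; bracket then bisect to band midpoint
    if a < lo_t:
        lo, hi = max(beta, b_lo), b_hi
        a_hi = achieved(hi)
        if a_hi < lo_t:
            raise CalibrationError(
                f"band {target_band} unreachable: AUC at beta={hi} is {a_hi:.3f}"
            )
    else:
        lo, hi = b_lo, min(beta, b_hi)
        a_lo = achieved(lo)
        if a_lo > hi_t:
            raise CalibrationError(
                f"band {target_band} unreachable: AUC at beta={lo} is {a_lo:.3f}"
            )
    target_mid = 0.5 * (lo_t + hi_t)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = achieved(mid)
        if lo_t <= a <= hi_t:
            return config.model_copy(update={"severity_beta": mid}), a
        if a < target_mid:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not land in {target_band} after {max_iter} iterations "
        f"(last AUC {a:.3f} at beta {mid:.3f})"
    )
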