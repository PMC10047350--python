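import numpy as np
import pytest
from pydantic import ValidationError

from ugib_scores.cohort import cohort_to_dataframe
from ugib_scores.scores import SCORE_FUNCTIONS, score_all
from ugib_scores.synthetic import (
    CalibrationError,
    SyntheticCohortConfig,
    calibrate_auc_band,
    generate_cohort,
    _score_auc,
)

NOENDO_ONLY = {"nonvariceal": 0.0, "variceal": 0.0, "no_endoscopy": 1.0}


def test_config_rejects_empty_cohort():
    with pytest.raises(ValidationError):
        SyntheticCohortConfig(n=0)


def test_config_rejects_degenerate_mortality_target():
    with pytest.raises(ValidationError, match="infeasible"):
        SyntheticCohortConfig(group_mortality={"nonvariceal": 0.0, "variceal": 0.2, "no_endoscopy": 0.4})


def test_config_rejects_missing_group_keys():
    with pytest.raises(ValidationError, match="keys"):
        SyntheticCohortConfig(group_mix={"variceal": 1.0})


def test_seed_determinism_identical_cohorts():
    cfg = SyntheticCohortConfig(n=150, seed=7)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert a.records == b.records
    assert cohort_to_dataframe(a).equals(cohort_to_dataframe(b))


def test_different_seeds_differ():
    a = generate_cohort(SyntheticCohortConfig(n=150, seed=7))
    b = generate_cohort(SyntheticCohortConfig(n=150, seed=8))
    assert a.records != b.records


def test_group_mortality_tracks_targets(noendo_cohort_4k):
    deaths = sum(r.outcome_death for r in noendo_cohort_4k)
    assert deaths / len(noendo_cohort_4k) == pytest.approx(0.379, abs=0.025)


def test_covariate_means_anchor_to_group_profiles(small_cohort):
    by_group = {}
    for r in small_cohort:
        by_group.setdefault(r.etiology_group.value, []).append(r)
    hb = {g: np.mean([r.hemoglobin for r in recs if r.hemoglobin is not None])
          for g, recs in by_group.items()}
    # anemia on admission in every group, ~8-9 g/dL
    assert all(7.5 < v < 9.5 for v in hb.values())
    urea = {g: np.mean([r.urea for r in recs if r.urea is not None])
            for g, recs in by_group.items()}
    assert urea["no_endoscopy"] > urea["variceal"]


def test_no_endoscopy_group_has_higher_mean_gbs_than_nonvariceal(small_cohort):
    means = {}
    for grp in ("no_endoscopy", "nonvariceal"):
        vals = [
            score_all(r)["glasgow_blatchford"].value
            for r in small_cohort
            if r.etiology_group.value == grp
        ]
        means[grp] = np.mean(vals)
    assert means["no_endoscopy"] > means["nonvariceal"]


def test_all_scores_discriminate_death(noendo_cohort_4k):
    """With a positive severity-death link every score, built from
    severity-loaded covariates, must beat chance."""
    for name in SCORE_FUNCTIONS:
        assert _score_auc(noendo_cohort_4k, name) > 0.5, name


def test_zero_beta_gives_chance_level_auc():
    cfg = SyntheticCohortConfig(n=4000, seed=9, severity_beta=0.0, group_mix=NOENDO_ONLY)
    cohort = generate_cohort(cfg)
    assert _score_auc(cohort, "inbs") == pytest.approx(0.5, abs=0.04)


def test_missingness_masks_fields_and_keeps_validity():
    cfg = SyntheticCohortConfig(n=400, seed=2, missingness_rate=0.2)
    cohort = generate_cohort(cfg)
    frac_missing = np.mean([r.albumin is None for r in cohort])
    assert 0.1 < frac_missing < 0.3
    # unusable scores are flagged, not zeroed
    res = [score_all(r)["aim65"] for r in cohort]
    assert any(not s.usable for s in res)
    assert all(s.value is not None for s in res if s.usable)


def test_calibrate_trivial_band_returns_config_unchanged():
    cfg = SyntheticCohortConfig(n=500, seed=3, group_mix=NOENDO_ONLY)
    out, achieved = calibrate_auc_band(cfg, "inbs", (0.5, 1.0), n_eval=2000)
    assert out == cfg
    assert 0.5 <= achieved <= 1.0


def test_calibrate_steers_beta_into_band():
    cfg = SyntheticCohortConfig(n=500, seed=3, severity_beta=0.3, group_mix=NOENDO_ONLY)
    out, achieved = calibrate_auc_band(cfg, "inbs", (0.70, 0.76), n_eval=4000)
    assert 0.70 <= achieved <= 0.76
    assert out.severity_beta > 0.3


def test_calibrate_unreachable_band_raises():
    cfg = SyntheticCohortConfig(n=500, seed=3, group_mix=NOENDO_ONLY)
    with pytest.raises(CalibrationError, match="unreachable"):
        calibrate_auc_band(cfg, "inbs", (0.995, 0.999), n_eval=2000, beta_bounds=(0.05, 3.0))


def test_unknown_score_name_rejected():
    with pytest.raises(KeyError):
        calibrate_auc_band(SyntheticCohortConfig(n=10), "apgar", (0.5, 1.0))
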