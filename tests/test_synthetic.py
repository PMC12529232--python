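"""Generator tests: calibration, determinism, marginal convergence, truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import trialtransport as tt
from trialtransport.synthetic import (calibrated_intercept, joint_covariate_table,
                                      load_config, save_config, solve_intercept)

from conftest import small_config


def test_default_config_reproduces_published_marginals(default_config):
    cfg = default_config
    assert cfg.trial_marginals["ethnicity"]["minority"] == pytest.approx(0.078, abs=1e-9)
    assert cfg.survey_specs[2021].covariate_marginals["lives_with_smoker"]["yes"] == \
        pytest.approx(0.281, abs=1e-9)
    assert cfg.survey_specs[2021].covariate_marginals["smoking_status"]["weekly"] == \
        pytest.approx(0.002, abs=1e-9)
    cfg.validate()  # every marginal sums to 1 by construction


def test_config_validation_catches_bad_inputs(default_config):
    cfg = tt.make_default_config()
    cfg.trial_marginals["gender"]["girl"] = 0.6
    with pytest.raises(ValueError):
        cfg.validate()
    cfg = tt.make_default_config()
    cfg.outcome_model.sigma_u = -0.1
    with pytest.raises(ValueError):
        cfg.validate()


def test_config_yaml_round_trip(tmp_path, default_config):
    path = tmp_path / "config.yaml"
    save_config(default_config, path)
    back = load_config(path)
    assert back.trial_marginals == default_config.trial_marginals
    assert back.survey_specs[2016].n_students == 4874
    assert back.outcome_model.treatment_log_or == pytest.approx(math.log(0.85))


def test_generate_schools_exact_arm_counts(default_config):
    schools = tt.generate_schools(default_config, "trial", seed=9)
    counts = schools["arm"].value_counts()
    assert counts["intervention"] == 30 and counts["control"] == 29
    again = tt.generate_schools(default_config, "trial", seed=9)
    pd.testing.assert_frame_equal(schools, again)


def test_generate_schools_block_balance_single_stratum():
    cfg = tt.make_default_config()
    cfg.trial_n_schools = 4
    cfg.trial_arm_school_counts = {"intervention": 2, "control": 2}
    cfg.strata_distribution = {v: {list(d)[0]: 1.0} for v, d in cfg.strata_distribution.items()}
    schools = tt.generate_schools(cfg, "trial", seed=0)
    assert schools["arm"].value_counts().to_dict() == {"intervention": 2, "control": 2}


def test_generate_schools_rejects_overfull_arms():
    cfg = tt.make_default_config()
    cfg.trial_arm_school_counts = {"intervention": 40, "control": 29}
    with pytest.raises(ValueError):
        tt.generate_schools(cfg, "trial", seed=0)


def test_solve_intercept_closed_forms():
    eta = np.zeros(1)
    probs = np.ones(1)
    assert solve_intercept(0.5, eta, probs, 0.0) == pytest.approx(0.0, abs=1e-9)
    alpha = solve_intercept(0.041, eta, probs, 0.0)
    assert alpha == pytest.approx(logit(0.041), abs=1e-8)


def test_solve_intercept_jensen_shift_matches_monte_carlo(rng):
    """With sigma_u = 1 the intercept must sit below logit(0.041)."""
    alpha = solve_intercept(0.041, np.zeros(1), np.ones(1), 1.0)
    assert alpha < logit(0.041)
    u = rng.normal(0, 1.0, 2_000_000)
    mc = expit(alpha + u).mean()
    assert mc == pytest.approx(0.041, abs=3 * 2e-4)


def test_solve_intercept_rejects_degenerate_targets():
    with pytest.raises(ValueError):
        solve_intercept(0.0, np.zeros(1), np.ones(1), 0.0)


def test_generate_trial_shape_and_determinism(default_config):
    trial = tt.generate_trial(default_config, seed=1)
    assert len(trial) == 8756
    assert trial["school_id"].nunique() == 59
    assert trial["arm"].value_counts().to_dict() == {"intervention": 4563, "control": 4193}
    assert set(trial["outcome_weekly"].unique()) <= {0.0, 1.0}
    pd.testing.assert_frame_equal(trial, tt.generate_trial(default_config, seed=1))


def test_null_effect_gives_symmetric_arms():
    cfg = small_config(n_trial=40000, n_schools=100)
    cfg.outcome_model.treatment_log_or = 0.0
    trial = tt.generate_trial(cfg, seed=21)
    prev = trial.groupby("arm", observed=True)["outcome_weekly"].mean()
    se = math.sqrt(2 * 0.041 * 0.959 / 20000) * 2.5  # cluster-inflated binomial scale
    assert abs(prev["intervention"] - prev["control"]) < 3 * se


@pytest.mark.parametrize("year,n", [(2004, 3958), (2006, 3377), (2014, 3145),
                                    (2016, 4874), (2021, 3587)])
def test_generate_survey_counts(default_config, year, n):
    sv = tt.generate_survey(default_config, year, seed=3)
    assert len(sv) == n
    assert sv["arm"].isna().all() and sv["outcome_weekly"].isna().all()
    assert "weekly" in set(sv["smoking_status"].unique()) or year == 2021


def test_generate_survey_determinism_and_unknown_year(default_config):
    a = tt.generate_survey(default_config, 2014, seed=8)
    b = tt.generate_survey(default_config, 2014, seed=8)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(KeyError):
        tt.generate_survey(default_config, 1999, seed=8)


def test_realized_marginals_converge_to_joint_law(default_config):
    """At n = 1e5 every marginal matches the configured joint law to 3 MC SEs."""
    cfg = tt.make_default_config()
    cfg.survey_specs[2004].n_students = 100_000
    cfg.survey_specs[2004].n_schools = 200
    sv = tt.generate_survey(cfg, 2004, seed=31)
    table = joint_covariate_table(cfg.survey_specs[2004].covariate_marginals,
                                  cfg.consistency_hook)
    for var in ("gender", "smoking_status", "ethnicity", "age",
                "age_first_cig", "lives_with_smoker", "lesson_smoking"):
        implied = table.groupby(var)["prob"].sum()
        for level, p in implied.items():
            if var == "lives_with_smoker":
                realized = (sv[var] == level).mean()  # no routing in 2004
            else:
                realized = (sv[var] == level).mean()
            se = math.sqrt(p * (1 - p) / len(sv))
            assert abs(realized - p) < 3 * se + 1e-9, (var, level)


@pytest.mark.parametrize("sigma_u", [0.0, 0.5, 1.0])
def test_calibrated_intercept_reproduces_target_prevalence(sigma_u):
    """Model-implied prevalence hits the calibration target for each sigma_u."""
    cfg = small_config(n_trial=100_000, n_schools=500)
    cfg.outcome_model.sigma_u = sigma_u
    trial = tt.generate_trial(cfg, seed=13)
    realized = trial["outcome_weekly"].mean()
    binom_se = math.sqrt(0.041 * 0.959 / len(trial))
    cluster_sd = 0.041 * sigma_u / math.sqrt(500)   # between-school component
    tol = 3 * math.sqrt(binom_se ** 2 + cluster_sd ** 2)
    assert abs(realized - cfg.outcome_model.target_prevalence) < tol


def test_true_estimand_homogeneous_is_analytic(default_config):
    est = tt.true_transported_estimand(default_config, 2021)
    assert est.method == "analytic"
    assert est.conditional_log_or_target == pytest.approx(math.log(0.85), abs=1e-15)
    cfg = tt.make_default_config()
    cfg.outcome_model.treatment_log_or = 0.0
    est0 = tt.true_transported_estimand(cfg, 2014)
    assert est0.conditional_log_or_target == 0.0


def test_true_estimand_interaction_attenuates_in_low_smoking_target():
    """Effect confined to baseline ever-smokers shrinks where few remain."""
    cfg = small_config()
    beta = math.log(0.7)
    # all effect in ever-smokers: never-smokers get the null
    cfg.outcome_model.treatment_log_or = beta
    cfg.outcome_model.interaction_log_or = {"smoking_status": {"never": -beta}}
    est = tt.true_transported_estimand(cfg, 2021, n=80_000, n_schools=100, seed=3)
    assert est.method == "brute_force"
    assert abs(est.conditional_log_or_target) < abs(beta)
    assert est.conditional_log_or_target < 0.05  # 2021: ~94% never-smokers
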