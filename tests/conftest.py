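import logging

import numpy as np
import pytest

import trialtransport as tt

logging.getLogger("trialtransport").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return tt.make_default_config()


@pytest.fixture(scope="session")
def small_trial():
    """A 3000-student, 30-school trial for fast model fits."""
    cfg = tt.make_default_config()
    cfg.trial_arm_school_counts = {"intervention": 15, "control": 15}
    cfg.trial_n_schools = 30
    cfg.trial_arm_student_counts = {"intervention": 1500, "control": 1500}
    return tt.generate_trial(cfg, seed=101)


@pytest.fixture(scope="session")
def small_survey(default_config):
    cfg = tt.make_default_config()
    cfg.survey_specs[2004].n_students = 2000
    cfg.survey_specs[2004].n_schools = 25
    return tt.generate_survey(cfg, 2004, seed=102).drop(columns=["routed"])


def small_config(n_trial=3000, n_schools=30, year=2004, n_target=2000, n_target_schools=25):
    cfg = tt.make_default_config()
    half_s, half_n = n_schools // 2, n_trial // 2
    cfg.trial_arm_school_counts = {"intervention": n_schools - half_s, "control": half_s}
    cfg.trial_n_schools = n_schools
    cfg.trial_arm_student_counts = {"intervention": n_trial - half_n, "control": half_n}
    cfg.survey_specs[year].n_students = n_target
    cfg.survey_specs[year].n_schools = n_target_schools
    return cfg


def shift_marginals(cfg, year, strength=1.0):
    """Blend a survey year's covariate law toward a strongly shifted one.

    strength 0 leaves the trial marginals (no shift); 1 applies the full
    designed shift on every weighting covariate.
    """
    strong = {
        "gender": {"boy": 0.40, "girl": 0.60},
        "smoking_status": {"never": 0.75, "occ_exp_ex": 0.23, "weekly": 0.02},
        "ethnicity": {"white": 0.75, "minority": 0.25},
        "age": {12: 0.45, 13: 0.55},
        "age_first_cig": {"never": 0.73, "le10": 0.06, "y11": 0.07, "y12": 0.09, "y13": 0.05},
        "lives_with_smoker": {"yes": 0.30, "no": 0.70},
        "lesson_smoking": {"yes": 0.70, "no": 0.15, "dont_know": 0.15},
    }
    base = cfg.trial_marginals
    blended = {
        var: {lvl: (1 - strength) * base[var][lvl] + strength * p
              for lvl, p in strong[var].items()}
        for var in strong
    }
    cfg.survey_specs[year].covariate_marginals = blended
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
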