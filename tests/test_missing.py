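"""Missing-data tests: amputation, MAR diagnostic, MI, Rubin pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trialtransport as tt
from trialtransport.missing import AmputationSpec

from conftest import small_config


@pytest.fixture(scope="module")
def complete_survey():
    cfg = small_config(n_trial=2000, year=2004, n_target=8000, n_target_schools=40)
    return tt.generate_survey(cfg, 2004, seed=201).drop(columns="routed")


# ---------------------------------------------------------------------------
# amputation

def test_amputate_rate_zero_is_identity(complete_survey):
    out = tt.amputate(complete_survey, [AmputationSpec("lesson_smoking", 0.0)], seed=1)
    pd.testing.assert_frame_equal(out, complete_survey)


def test_amputate_mcar_hits_target_rate(complete_survey):
    out = tt.amputate(complete_survey, [AmputationSpec("lives_with_smoker", 0.2)], seed=2)
    rate = out["lives_with_smoker"].isna().mean()
    se = math.sqrt(0.2 * 0.8 / len(out))
    assert rate == pytest.approx(0.2, abs=3 * se)
    # everything else untouched
    assert out["lesson_smoking"].notna().all()


def test_amputate_mar_direction_matches_mechanism(complete_survey):
    spec = AmputationSpec("lesson_smoking", 0.2, predictors={"gender": {"girl": 1.0}})
    out = tt.amputate(complete_survey, [spec], seed=3)
    rate_girl = out.loc[out["gender"] == "girl", "lesson_smoking"].isna().mean()
    rate_boy = out.loc[out["gender"] == "boy", "lesson_smoking"].isna().mean()
    # realized log-odds difference matches the mechanism's log-OR of 1
    lo = math.log(rate_girl / (1 - rate_girl)) - math.log(rate_boy / (1 - rate_boy))
    assert lo == pytest.approx(1.0, abs=0.3)


def test_amputate_rejects_mnar(complete_survey):
    spec = AmputationSpec("gender", 0.2, predictors={"gender": {"girl": 1.0}})
    with pytest.raises(ValueError):
        tt.amputate(complete_survey, [spec], seed=4)


# ---------------------------------------------------------------------------
# MAR diagnostic

def test_diagnostic_mcar_finds_no_signal(complete_survey):
    out = tt.amputate(complete_survey, [AmputationSpec("lesson_smoking", 0.2)], seed=5)
    rep = tt.missingness_diagnostic(out, "lesson_smoking")
    coefs = rep["coefficients"].drop(index="intercept")
    assert (coefs["coef"].abs() < 3 * coefs["se"] + 1e-12).mean() >= 0.9


def test_diagnostic_recovers_mar_mechanism(complete_survey):
    spec = AmputationSpec("lesson_smoking", 0.25, predictors={"gender": {"girl": 1.0}})
    out = tt.amputate(complete_survey, [spec], seed=6)
    rep = tt.missingness_diagnostic(out, "lesson_smoking")
    row = rep["coefficients"].loc["gender[girl]"]
    assert row["coef"] == pytest.approx(1.0, abs=3 * row["se"])


def test_diagnostic_rejects_degenerate_variables(complete_survey):
    with pytest.raises(ValueError):
        tt.missingness_diagnostic(complete_survey, "gender")  # fully observed
    allmiss = complete_survey.copy()
    allmiss["lesson_smoking"] = np.nan
    with pytest.raises(ValueError):
        tt.missingness_diagnostic(allmiss, "lesson_smoking")


# ---------------------------------------------------------------------------
# imputation

def test_impute_identity_without_missingness(complete_survey):
    imps = tt.impute(complete_survey, m=3, seed=7)
    assert imps.m == 3
    for df in imps.completed_datasets:
        pd.testing.assert_frame_equal(df, complete_survey)


def test_impute_is_deterministic_and_preserves_observed(complete_survey):
    out = tt.amputate(complete_survey, [AmputationSpec("lives_with_smoker", 0.2)], seed=8)
    a = tt.impute(out, m=2, seed=9)
    b = tt.impute(out, m=2, seed=9)
    for da, db in zip(a.completed_datasets, b.completed_datasets):
        pd.testing.assert_frame_equal(da, db)
    # no dataset retains missing values; observed cells untouched (asserted
    # internally by impute); imputations differ across m
    assert not a.completed_datasets[0]["lives_with_smoker"].isna().any()
    assert not a.completed_datasets[0].equals(a.completed_datasets[1])


@pytest.mark.parametrize("method", ["chained_equations", "multivariate_normal"])
def test_impute_mcar_preserves_category_proportions(complete_survey, method):
    out = tt.amputate(complete_survey, [AmputationSpec("lives_with_smoker", 0.2)], seed=10)
    observed_prop = (out["lives_with_smoker"] == "yes").sum() / out["lives_with_smoker"].notna().sum()
    imps = tt.impute(out, m=5, seed=11, method=method)
    props = [(df["lives_with_smoker"] == "yes").mean() for df in imps.completed_datasets]
    se = math.sqrt(observed_prop * (1 - observed_prop) / len(out))
    assert np.mean(props) == pytest.approx(observed_prop, abs=5 * se)


def test_impute_rejects_bad_inputs(complete_survey):
    with pytest.raises(ValueError):
        tt.impute(complete_survey, m=1, seed=0)
    allmiss = complete_survey.copy()
    allmiss["lesson_smoking"] = np.nan
    with pytest.raises(ValueError):
        tt.impute(allmiss, variables=["lesson_smoking"], m=2, seed=0)


# ---------------------------------------------------------------------------
# Rubin's rules

def test_pool_rubin_hand_example():
    pooled = tt.pool_rubin([0.1, 0.2, 0.3], [0.04, 0.04, 0.04])
    assert pooled.qbar == pytest.approx(0.2)
    assert pooled.within_var == pytest.approx(0.04)
    assert pooled.between_var == pytest.approx(0.01)
    assert pooled.total_var == pytest.approx(0.04 + (4 / 3) * 0.01)
    assert pooled.mcse == pytest.approx(math.sqrt(0.01 / 3))


def test_pool_rubin_degenerate_and_errors():
    pooled = tt.pool_rubin([0.0, 0.0], [1.0, 1.0])
    assert pooled.qbar == 0.0 and pooled.total_var == pytest.approx(1.0)
    assert pooled.between_var == 0.0 and pooled.mcse == 0.0
    assert math.isinf(pooled.df)
    with pytest.raises(ValueError):
        tt.pool_rubin([0.1], [0.04])
    with pytest.raises(ValueError):
        tt.pool_rubin([0.1, 0.2], [0.04, -0.01])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=2, max_size=20),
       st.data())
def test_pool_rubin_total_dominates_within(qs, data):
    us = data.draw(st.lists(st.floats(1e-3, 10), min_size=len(qs), max_size=len(qs)))
    pooled = tt.pool_rubin(qs, us)
    assert pooled.total_var >= pooled.within_var - 1e-12
    assert pooled.m == len(qs)
    if pooled.between_var == 0:
        assert pooled.mcse == 0.0


def test_barnard_rubin_df_below_large_sample_df():
    big = tt.pool_rubin([0.1, 0.2, 0.3], [0.04, 0.04, 0.04])
    small = tt.pool_rubin([0.1, 0.2, 0.3], [0.04, 0.04, 0.04], nu_com=30)
    assert small.df < big.df


def test_monte_carlo_error_check_flags_and_m_scaling(rng):
    ok = tt.monte_carlo_error_check(tt.pool_rubin([0.2, 0.2], [0.04, 0.04]))
    assert not ok["flag_more_imputations_needed"] and ok["mcse"] == 0.0
    bad = tt.monte_carlo_error_check(tt.pool_rubin([0.0, 2.0], [0.01, 0.01]))
    assert bad["flag_more_imputations_needed"]
    # doubling m shrinks the Monte Carlo error on average
    mcse10, mcse40 = [], []
    for _ in range(200):
        mcse10.append(tt.pool_rubin(rng.normal(0, 1, 10), np.ones(10)).mcse)
        mcse40.append(tt.pool_rubin(rng.normal(0, 1, 40), np.ones(40)).mcse)
    assert np.mean(mcse40) < np.mean(mcse10)


# ---------------------------------------------------------------------------
# MI end-to-end recovery

def test_mi_recovers_complete_data_transported_estimate():
    """MAR amputation at 20% on two covariates, impute, pool: the pooled
    transported log-OR stays within 3 SEs of the no-missingness estimate."""
    cfg = small_config(n_trial=6000, n_schools=40, n_target=4000)
    trial = tt.generate_trial(cfg, seed=202)
    survey = tt.generate_survey(cfg, 2004, seed=202).drop(columns="routed")

    def transported(tr, sv):
        stacked = tt.stack_datasets(tr, sv, 2004)
        sel = tt.fit_selection_model(stacked)
        p = tt.predict_selection_prob(sel, stacked.records)
        ws = tt.inverse_odds_weights(p, stacked.S == 1, year=2004)
        rows = stacked.records[stacked.records["S"] == 1].reset_index(drop=True)
        return tt.fit_transported_effect(rows, ws)

    full = transported(trial, survey)
    specs = [
        AmputationSpec("lives_with_smoker", 0.2, predictors={"gender": {"girl": 0.7}}),
        AmputationSpec("lesson_smoking", 0.2, predictors={"age": {13: 0.7}}),
    ]
    sv_miss = tt.amputate(survey, specs, seed=203)
    imps = tt.impute(sv_miss, m=5, seed=204)
    ests = [transported(trial, sv) for sv in imps.completed_datasets]
    pooled = tt.pool_rubin([e.log_or for e in ests], [e.se ** 2 for e in ests])
    assert pooled.qbar == pytest.approx(full.log_or, abs=3 * math.sqrt(pooled.total_var))
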