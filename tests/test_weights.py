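"""Selection model and inverse-odds weighting tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import trialtransport as tt
from trialtransport.glmm import SeparationError
from trialtransport.synthetic import joint_covariate_table
from trialtransport.weights import predict_selection_prob_conditional

from conftest import shift_marginals, small_config


def _stacked(seed=61, strength=None, n_trial=3000, n_target=3000, year=2004):
    cfg = small_config(n_trial=n_trial, year=year, n_target=n_target)
    if strength is None:
        cfg.survey_specs[year].covariate_marginals = {
            v: dict(d) for v, d in cfg.trial_marginals.items()
        }
    else:
        shift_marginals(cfg, year, strength)
    trial = tt.generate_trial(cfg, seed=seed)
    survey = tt.generate_survey(cfg, year, seed=seed).drop(columns="routed")
    return cfg, tt.stack_datasets(trial, survey, year)


def test_exchangeable_populations_give_null_model_and_flat_weights():
    """Identical covariate laws: coefficients ~0, intercept ~logit(share),
    weights concentrate near n_target/n_trial, weighted means unchanged."""
    cfg, stacked = _stacked(seed=61, strength=None, n_trial=6000, n_target=6000)
    sel = tt.fit_selection_model(stacked)
    table = sel.coefficient_table()
    coef = table.drop(index="intercept")
    assert (coef["coef"].abs() < 3 * coef["se"] + 1e-12).all()
    share = stacked.n_trial / len(stacked.records)
    assert table.loc["intercept", "coef"] == pytest.approx(
        logit(share), abs=3 * table.loc["intercept", "se"])
    p = tt.predict_selection_prob(sel, stacked.records)
    ws = tt.inverse_odds_weights(p, stacked.S == 1, year=2004)
    ratio = stacked.n_target / stacked.n_trial
    assert np.quantile(ws.weights, [0.05, 0.95]) == pytest.approx(ratio, rel=0.25)
    trial_rows = stacked.records[stacked.records["S"] == 1]
    for var, lvl in [("gender", "girl"), ("smoking_status", "weekly")]:
        unw = (trial_rows[var] == lvl).mean()
        wm = np.average(trial_rows[var] == lvl, weights=ws.weights)
        assert wm == pytest.approx(unw, abs=0.02)


def test_single_covariate_matches_2x2_cross_product_ratio():
    """No clustering effect: the gender coefficient equals the log
    cross-product ratio of the S-by-gender table (closed-form MLE)."""
    _, stacked = _stacked(seed=62, strength=1.0)
    sel = tt.fit_selection_model(stacked, covariates=["gender"])
    df = stacked.records
    a = ((df["S"] == 1) & (df["gender"] == "girl")).sum()
    b = ((df["S"] == 1) & (df["gender"] == "boy")).sum()
    c = ((df["S"] == 0) & (df["gender"] == "girl")).sum()
    d = ((df["S"] == 0) & (df["gender"] == "boy")).sum()
    expected = math.log((a * d) / (b * c))
    assert sel.coefficient_table().loc["gender[girl]", "coef"] == pytest.approx(expected, abs=1e-6)


def test_source_exclusive_level_is_a_positivity_failure():
    _, stacked = _stacked(seed=63)
    records = stacked.records.copy()
    # make 'minority' a target-only level
    records.loc[records["S"] == 1, "ethnicity"] = "white"
    broken = tt.StackedDataset(records=records, year=stacked.year)
    with pytest.raises(SeparationError):
        tt.fit_selection_model(broken)


def test_inverse_odds_closed_forms_and_boundaries():
    p = np.array([0.5, 0.2, 0.8, 0.4])
    mask = np.array([True, True, False, True])
    ws = tt.inverse_odds_weights(p, mask)
    np.testing.assert_allclose(ws.weights, [(1 - 0.5) / 0.5, (1 - 0.2) / 0.2, (1 - 0.4) / 0.4])
    assert ws.weights[1] == pytest.approx(4.0)
    with pytest.raises(SeparationError):
        tt.inverse_odds_weights(np.array([1.0, 0.5]), np.array([True, True]))
    # ESS bounds: <= n, equality iff equal weights
    assert ws.ess <= mask.sum()
    flat = tt.inverse_odds_weights(np.full(5, 0.3), np.ones(5, bool))
    assert flat.ess == pytest.approx(5.0)


def test_truncation_and_normalization_options():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.95, 500)
    ws = tt.inverse_odds_weights(p, np.ones(500, bool), truncation=(1, 99))
    raw = (1 - p) / p
    assert ws.weights.max() <= np.percentile(raw, 99) + 1e-12
    wn = tt.inverse_odds_weights(p, np.ones(500, bool), normalize=True)
    assert wn.weights.mean() == pytest.approx(1.0)


def test_true_inverse_odds_recover_target_covariate_distribution():
    """Weighting the trial by generator-known inverse odds reproduces the
    target covariate marginals (3 MC SEs at n = 50 000)."""
    cfg = small_config(n_trial=50_000, n_schools=120, n_target=2000)
    shift_marginals(cfg, 2004, 1.0)
    trial = tt.generate_trial(cfg, seed=64)
    t_tab = joint_covariate_table(cfg.trial_marginals, True)
    g_tab = joint_covariate_table(cfg.survey_specs[2004].covariate_marginals, True)
    covs = list(t_tab.columns.drop("prob"))
    key_t = t_tab[covs].astype(str).agg("|".join, axis=1)
    key_g = g_tab[covs].astype(str).agg("|".join, axis=1)
    dens_t = dict(zip(key_t, t_tab["prob"]))
    dens_g = dict(zip(key_g, g_tab["prob"]))
    key = trial[covs].astype(str).agg("|".join, axis=1)
    w = key.map(lambda k: dens_g.get(k, 0.0) / dens_t[k]).to_numpy()
    keep = w > 0
    target = cfg.survey_specs[2004].covariate_marginals
    for var in ("gender", "smoking_status", "lives_with_smoker", "ethnicity"):
        implied = g_tab.groupby(var)["prob"].sum()
        for lvl, p_lvl in implied.items():
            wm = np.average((trial.loc[keep, var] == lvl), weights=w[keep])
            se = math.sqrt(p_lvl * (1 - p_lvl) / 50_000) * 3  # weighted SE is larger
            assert wm == pytest.approx(p_lvl, abs=3 * se + 0.005), (var, lvl)


def test_positivity_report_flags_and_ess_monotonicity():
    _, st_ok = _stacked(seed=65, strength=None)
    sel = tt.fit_selection_model(st_ok)
    p = tt.predict_selection_prob(sel, st_ok.records)
    ws = tt.inverse_odds_weights(p, st_ok.S == 1)
    rep = tt.positivity_report(ws, st_ok)
    assert rep["positivity_ok"] and rep["flagged_cells"] == []

    # target-only cell: flag without any estimate
    recs = st_ok.records.copy()
    recs.loc[recs["S"] == 1, "ethnicity"] = "white"
    broken = tt.StackedDataset(records=recs, year=st_ok.year)
    rep2 = tt.positivity_report(ws, broken)
    assert not rep2["positivity_ok"]
    assert any(c["variable"] == "ethnicity" and c["level"] == "minority"
               for c in rep2["flagged_cells"])

    # ESS falls as covariate shift grows (same seed, paired comparison)
    ess = []
    for strength in (0.3, 1.0):
        _, st = _stacked(seed=66, strength=strength)
        sel_s = tt.fit_selection_model(st)
        p_s = tt.predict_selection_prob(sel_s, st.records)
        ess.append(tt.inverse_odds_weights(p_s, st.S == 1).ess)
    assert ess[1] < ess[0]


def test_marginal_and_conditional_prediction_modes():
    """With sigma_u = 0 the two prediction modes coincide."""
    _, stacked = _stacked(seed=67, strength=0.5)
    sel = tt.fit_selection_model(stacked)
    assert sel.random_intercept_sd == 0.0
    p_m = tt.predict_selection_prob(sel, stacked.records)
    p_c = predict_selection_prob_conditional(sel, stacked)
    np.testing.assert_allclose(p_m, p_c, atol=1e-10)
    assert ((p_m > 0) & (p_m < 1)).all()


def test_unseen_level_prediction_is_an_error():
    _, stacked = _stacked(seed=68)
    df = stacked.records.copy()
    df = df[df["age_first_cig"] != "y13"].reset_index(drop=True)
    st = tt.StackedDataset(records=df, year=2004)
    sel = tt.fit_selection_model(st)
    with pytest.raises(ValueError):
        tt.predict_selection_prob(sel, stacked.records)
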