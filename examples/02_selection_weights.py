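"""Fit the selection model and inspect the inverse odds of selection weights.

Stacks the trial on top of one survey wave, models the probability of
being a trial (rather than survey) participant given the harmonized
covariates, and weights each trial student by the inverse odds
(1 - p) / p. The effective sample size shows how much information the
weighting costs; the positivity report lists any target covariate cells
with no trial counterpart.
"""

import numpy as np

import trialtransport as tt

cfg = tt.make_default_config()
trial = tt.generate_trial(cfg, seed=2)
survey = tt.generate_survey(cfg, 2004, seed=2).drop(columns="routed")

stacked = tt.stack_datasets(trial, survey, 2004)
sel = tt.fit_selection_model(stacked)
print("selection model coefficients (log-odds of being a trial participant):")
print(sel.coefficient_table().round(3))

p = tt.predict_selection_prob(sel, stacked.records)
ws = tt.inverse_odds_weights(p, stacked.S == 1, year=2004)
print(f"\nweights: mean {ws.weights.mean():.3f} "
      f"(n_target/n_trial = {stacked.n_target / stacked.n_trial:.3f})")
print(f"effective sample size: {ws.ess:.0f} of {stacked.n_trial} trial students")

rep = tt.positivity_report(ws, stacked)
print(f"positivity ok: {rep['positivity_ok']} ({len(rep['flagged_cells'])} flagged cells)")

# the weighted trial should look like the target population
rows = stacked.records[stacked.records["S"] == 1]
for var, lvl in [("smoking_status", "weekly"), ("ethnicity", "minority")]:
    weighted = np.average(rows[var] == lvl, weights=ws.weights)
    target = (stacked.records.loc[stacked.S == 0, var] == lvl).mean()
    print(f"{var}[{lvl}]: weighted trial {100 * weighted:.1f}% vs target {100 * target:.1f}%")
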