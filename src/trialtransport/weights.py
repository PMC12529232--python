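"""Selection model and inverse odds of selection weights.

Trial participation is modelled with a school random-intercept logistic
regression of the selection indicator S (1 = trial, 0 = target) on the
harmonized covariates, fitted on the stacked dataset.  Each trial
participant then receives the inverse odds of selection

    w_i = (1 - p_i) / p_i,

where p_i is the modelled probability of being a trial rather than a
target participant given covariates.  Weighted this way, the trial
covariate distribution matches the target population's, which is what
makes the weighted trial effect a transported effect.

Selection probabilities are, by default, marginal over the school random
intercept: target-population schools carry no estimated trial random
effect, so the marginal probability is the defensible default; a
conditional (empirical-Bayes mode per school) option is exposed for
sensitivity analyses.

Positivity diagnostics report the effective sample size, the range of
fitted probabilities, and covariate cells present in the target but
empty in either trial arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import design_matrix
from .glmm import MixedLogitFit, SeparationError, empirical_bayes_modes, fit_mixed_logit, marginal_prob
from .harmonize import SELECTION_COVARIATES, StackedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionModelFit", "WeightSet", "fit_selection_model",
    "predict_selection_prob", "inverse_odds_weights", "positivity_report",
]


@dataclass
class SelectionModelFit:
    """Multilevel logistic fit of trial membership on covariates."""

    fit: MixedLogitFit
    covariates: list[str]
    names: list[str]
    year: int
    n_used: int

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def random_intercept_sd(self) -> float:
        return self.fit.sigma_u

    def coefficient_table(self) -> pd.DataFrame:
        se = self.fit.bse("model")
        return pd.DataFrame(
            {"coef": self.fit.params, "se": se,
             "z": self.fit.params / np.where(se > 0, se, np.nan)},
            index=self.names,
        )


@dataclass
class WeightSet:
    """Inverse-odds weights for the trial rows of one stacked dataset."""

    weights: np.ndarray            # one per trial record, stacking order
    selection_probs: np.ndarray
    year: int
    truncation: tuple[float, float] | None = None
    normalized: bool = False

    @property
    def ess(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / np.sum(w ** 2))

    @property
    def min_p(self) -> float:
        return float(self.selection_probs.min())

    @property
    def max_p(self) -> float:
        return float(self.selection_probs.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.selection_probs, "w": self.weights})


def fit_selection_model(
    stacked: StackedDataset,
    covariates: list[str] | None = None,
    n_quad: int = 15,
) -> SelectionModelFit:
    """Fit the school random-intercept selection model on stacked data.

    Requires complete covariates (imputation happens upstream) and at
    least two schools per source.  Perfect separation — e.g. a covariate
    level present only among trial rows — is raised as a
    :class:`~trialtransport.glmm.SeparationError`, i.e. reported as a
    positivity failure rather than silently regularized.
    """
    covariates = list(covariates) if covariates is not None else list(SELECTION_COVARIATES)
    df = stacked.records
    for src in ("trial", "target"):
        n_sch = df.loc[df["source"] == src, "school_id"].nunique()
        if n_sch < 2:
            raise ValueError(f"need >= 2 {src} schools, found {n_sch}")
    X, names = design_matrix(df, covariates)
    y = df["S"].to_numpy(dtype=float)
    groups = df["school_id"].to_numpy()
    # When trial and target schools are disjoint (the usual design), S is
    # constant within every school and a school random intercept is
    # unidentified: its ML variance diverges and absorbs S entirely.  In
    # that case the selection model drops to a single-level logistic fit.
    s_varies_within = df.groupby("school_id", sort=False)["S"].nunique().gt(1).any()
    if not s_varies_within:
        logger.warning("selection indicator is school-constant; random intercept "
                       "unidentified, fitting single-level selection model")
        groups = None
    fit = fit_mixed_logit(X, y, groups=groups, names=names, n_quad=n_quad)
    if not fit.converged:
        raise RuntimeError("selection model did not converge")
    logger.info("selection model (year %s): n=%d, sigma_u=%.3f", stacked.year, fit.n, fit.sigma_u)
    return SelectionModelFit(fit=fit, covariates=covariates, names=fit.names,
                             year=stacked.year, n_used=fit.n)


def predict_selection_prob(
    sel: SelectionModelFit,
    records: pd.DataFrame,
    mode: str = "marginal",
    n_quad: int = 25,
) -> np.ndarray:
    """Selection probability per record.

    ``marginal`` (default) integrates the school random intercept out by
    quadrature; ``conditional`` plugs in each school's empirical-Bayes
    mode (schools unseen at fit time get 0).
    """
    if not sel.converged:
        raise RuntimeError("refusing to predict from a non-converged selection model")
    X, names = design_matrix(records, sel.covariates, drop_constant=False)
    X = _align_columns(X, names, sel.names, sel.fit.aliased)
    if mode == "marginal":
        p = marginal_prob(X, sel.fit.params, sel.fit.sigma_u, n_quad=n_quad)
    elif mode == "conditional":
        raise ValueError("conditional prediction needs the fitting data; use predict_selection_prob_conditional")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.asarray(p, float)


def predict_selection_prob_conditional(
    sel: SelectionModelFit,
    stacked: StackedDataset,
) -> np.ndarray:
    """Conditional selection probabilities at the schools' EB modes."""
    df = stacked.records
    X, names = design_matrix(df, sel.covariates, drop_constant=False)
    X = _align_columns(X, names, sel.names, sel.fit.aliased)
    modes = empirical_bayes_modes(sel.fit, X, df["S"].to_numpy(float), df["school_id"].to_numpy())
    u = df["school_id"].map(modes).fillna(0.0).to_numpy()
    return np.asarray(sel.fit.predict_conditional(X, u), float)


def _align_columns(X: np.ndarray, names: list[str], target_names: list[str],
                   aliased: list[str] | None = None) -> np.ndarray:
    """Reindex design columns onto the fitted coefficient order.

    A column the fit used but the new data lacks becomes all-zero; a
    column aliased (collinear) at fit time contributes zero; a level
    unseen at fit time is an error (its coefficient is undefined).
    """
    known = set(target_names) | set(aliased or [])
    extra = [nm for nm, col in zip(names, X.T) if nm not in known and col.any()]
    if extra:
        raise ValueError(f"covariate levels unseen in the selection fit: {extra}")
    out = np.zeros((X.shape[0], len(target_names)))
    pos = {nm: j for j, nm in enumerate(names)}
    for j, nm in enumerate(target_names):
        if nm in pos:
            out[:, j] = X[:, pos[nm]]
    return out


def inverse_odds_weights(
    selection_probs: np.ndarray,
    trial_mask: np.ndarray,
    year: int = 0,
    truncation: tuple[float, float] | None = None,
    normalize: bool = False,
) -> WeightSet:
    """Inverse odds of selection weights for the trial rows.

    Target rows receive no weight (they do not enter the outcome model).
    Probabilities on the boundary are a positivity failure.  Optional
    symmetric percentile truncation (e.g. ``(1, 99)``) clips extreme
    weights for diagnostics; weights are left unnormalized by default.
    """
    p = np.asarray(selection_probs, float)
    mask = np.asarray(trial_mask, bool)
    if p.shape[0] != mask.shape[0]:
        raise ValueError("selection_probs and trial_mask lengths differ")
    p_trial = p[mask]
    if np.any((p_trial <= 0.0) | (p_trial >= 1.0)):
        raise SeparationError("selection probabilities on {0,1} boundary: positivity failure")
    w = (1.0 - p_trial) / p_trial
    if truncation is not None:
        lo, hi = np.percentile(w, truncation)
        w = np.clip(w, lo, hi)
    if normalize:
        w = w / w.mean()
    return WeightSet(weights=w, selection_probs=p_trial, year=year,
                     truncation=truncation, normalized=normalize)


def positivity_report(
    weightset: WeightSet,
    stacked: StackedDataset,
    covariates: list[str] | None = None,
) -> dict:
    """Positivity and overlap diagnostics for one transported analysis.

    Reports the effective sample size, weight quantiles and probability
    range, plus every single-covariate level present in the target but
    empty in either trial arm (a population-positivity violation for
    that cell).
    """
    covariates = list(covariates) if covariates is not None else list(SELECTION_COVARIATES)
    df = stacked.records
    trial = df[df["S"] == 1]
    target = df[df["S"] == 0]
    flagged = []
    for var in covariates:
        tgt_levels = set(target[var].dropna().unique())
        for level in sorted(map(str, tgt_levels)):
            for arm in ("control", "intervention"):
                arm_rows = trial[trial["arm"] == arm]
                if not (arm_rows[var].astype(str) == level).any():
                    flagged.append({"variable": var, "level": level, "missing_in_arm": arm})
    w = weightset.weights
    report = {
        "year": int(stacked.year),
        "n_trial": int(len(trial)),
        "n_target": int(len(target)),
        "ess": weightset.ess,
        "min_p": weightset.min_p,
        "max_p": weightset.max_p,
        "weight_quantiles": {
            str(q): float(np.quantile(w, q)) for q in (0.0, 0.01, 0.25, 0.5, 0.75, 0.99, 1.0)
        },
        "flagged_cells": flagged,
        "positivity_ok": len(flagged) == 0,
    }
    if flagged:
        logger.warning("positivity: %d covariate cells flagged for year %s", len(flagged), stacked.year)
    return report
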