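"""Intervention-effect estimation on weekly smoking.

Two fits share one engine (:mod:`trialtransport.glmm`):

* the within-trial effect — a school random-intercept logistic
  regression of the follow-up outcome on arm, adjusting for the
  school-level stratification variables used at randomization;
* the transported effect — the same model fitted by weighted
  pseudo-likelihood with inverse-odds-of-selection weights, variance by
  a cluster-robust (school-level) sandwich, which is conservative with
  respect to the estimation noise in the weights.

Weights are rescaled to mean 1 inside the weighted fit by default.  For
a pseudo-likelihood mixed model the overall weight scale is not
innocuous (unlike a plain weighted GLM), and mean-1 scaling both pins
that choice down and makes the point estimate invariant to rescaling
the input weights by any constant.  ``weight_scaling="none"`` keeps raw
(frequency) semantics, under which integer weights reproduce the fit on
a row-replicated dataset exactly.

Effects are reported as odds ratios with Wald 95% intervals on the
log-odds scale, plus the confidence interval ratio (upper limit over
lower limit), a scale-free precision measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import design_matrix
from .glmm import fit_mixed_logit
from .harmonize import STRATIFICATION_VARIABLES
from .weights import WeightSet

logger = logging.getLogger(__name__)

__all__ = ["EffectEstimate", "fit_trial_effect", "fit_transported_effect", "ci_ratio"]

_Z95 = 1.959963984540054


def ci_ratio(ci_low: float, ci_high: float) -> float:
    """Confidence interval ratio: upper limit divided by lower limit."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("confidence limits must be positive")
    if ci_high < ci_low:
        raise ValueError("upper limit below lower limit")
    return ci_high / ci_low


@dataclass
class EffectEstimate:
    """One arm-effect estimate (odds-ratio scale with 95% CI)."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    ci_ratio: float
    n: int
    n_schools: int
    weighted: bool
    year: int | None = None   # None marks the within-trial estimate
    sigma_u: float | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_wald(cls, log_or: float, se: float, z: float = _Z95, **kw) -> "EffectEstimate":
        lo = float(np.exp(log_or - z * se))
        hi = float(np.exp(log_or + z * se))
        return cls(log_or=float(log_or), se=float(se), or_=float(np.exp(log_or)),
                   ci_low=lo, ci_high=hi, ci_ratio=ci_ratio(lo, hi), **kw)


def _usable_strat_vars(trial: pd.DataFrame, strat_vars: list[str]) -> list[str]:
    """Drop stratification variables with a single-school level.

    A stratum level represented by one school (or none) cannot support a
    fixed-effect contrast on top of the school random intercept; such
    variables are merged out with a logged warning.
    """
    keep = []
    schools = trial.drop_duplicates("school_id")
    for var in strat_vars:
        counts = schools[var].value_counts(dropna=False)
        if len(counts) < 2:
            logger.warning("stratification variable %r constant across schools; dropped", var)
            continue
        if counts.min() < 2:
            logger.warning("stratification variable %r has a single-school level; merged (dropped)", var)
            continue
        keep.append(var)
    return keep


def _prepare_outcome_design(trial: pd.DataFrame, strat_vars: list[str]):
    if trial["outcome_weekly"].isna().any():
        raise ValueError("trial rows with missing outcome; filter or impute upstream")
    y = trial["outcome_weekly"].to_numpy(dtype=float)
    for arm in ("control", "intervention"):
        sub = y[(trial["arm"] == arm).to_numpy()]
        if len(sub) == 0:
            raise ValueError(f"no rows in arm {arm!r}")
        if sub.min() == sub.max():
            raise ValueError(f"outcome constant in arm {arm!r}: no information on the effect")
    strat_vars = _usable_strat_vars(trial, strat_vars) if strat_vars else []
    X, names = design_matrix(trial, strat_vars)
    arm = (trial["arm"] == "intervention").to_numpy(dtype=float)
    X = np.column_stack([X[:, :1], arm, X[:, 1:]])
    names = [names[0], "arm[intervention]"] + names[1:]
    groups = trial["school_id"].to_numpy()
    return X, names, y, groups


def fit_trial_effect(
    trial: pd.DataFrame,
    strat_vars: list[str] | None = None,
    n_quad: int = 15,
) -> EffectEstimate:
    """Unweighted random-intercept logistic fit of the trial effect.

    The arm coefficient is exponentiated to an odds ratio with a Wald
    95% interval from the observed-information standard error.
    """
    strat_vars = list(strat_vars) if strat_vars is not None else list(STRATIFICATION_VARIABLES)
    n_sch = trial.groupby("arm", observed=True)["school_id"].nunique()
    if (n_sch < 2).any():
        raise ValueError(f"need >= 2 schools per arm, got {n_sch.to_dict()}")
    X, names, y, groups = _prepare_outcome_design(trial, strat_vars)
    fit = fit_mixed_logit(X, y, groups=groups, names=names, n_quad=n_quad,
                          raise_on_separation=False)
    if not fit.converged:
        raise RuntimeError("trial effect model did not converge")
    j = names.index("arm[intervention]")
    se = float(np.sqrt(fit.cov_model[j, j]))
    return EffectEstimate.from_wald(
        fit.params[j], se, n=fit.n, n_schools=fit.n_groups,
        weighted=False, year=None, sigma_u=fit.sigma_u, converged=fit.converged,
    )


def fit_transported_effect(
    trial: pd.DataFrame,
    weights: WeightSet | np.ndarray,
    strat_vars: list[str] | None = None,
    weight_scaling: str = "mean_one",
    n_quad: int = 15,
    year: int | None = None,
) -> EffectEstimate:
    """Weighted pseudo-likelihood fit of the transported trial effect.

    ``weights`` must align one-to-one with the trial rows (stacking
    order is the trial row order).  Variance is the school-level
    cluster-robust sandwich.
    """
    strat_vars = list(strat_vars) if strat_vars is not None else list(STRATIFICATION_VARIABLES)
    if isinstance(weights, WeightSet):
        if year is None:
            year = weights.year
        w = np.asarray(weights.weights, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != len(trial):
        raise ValueError(f"{len(w)} weights for {len(trial)} trial rows")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if weight_scaling == "mean_one":
        w = w / w.mean()
    elif weight_scaling != "none":
        raise ValueError(f"unknown weight_scaling {weight_scaling!r}")

    X, names, y, groups = _prepare_outcome_design(trial, strat_vars)
    fit = fit_mixed_logit(X, y, groups=groups, weights=w, names=names, n_quad=n_quad,
                          raise_on_separation=False)
    if not fit.converged:
        raise RuntimeError("transported effect model did not converge")
    j = names.index("arm[intervention]")
    cov = fit.cov_cluster if fit.cov_cluster is not None else fit.cov_model
    if fit.cov_cluster is None:
        logger.warning("single cluster: falling back to model-based variance")
    se = float(np.sqrt(cov[j, j]))
    return EffectEstimate.from_wald(
        fit.params[j], se, n=fit.n, n_schools=fit.n_groups,
        weighted=True, year=year, sigma_u=fit.sigma_u, converged=fit.converged,
    )
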