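"""Missing data: diagnostics, multiple imputation and Rubin pooling.

The harmonized schema is all-categorical, so the default imputer is
chained equations with multinomial-logistic conditional models; each
imputation refits the conditionals on a bootstrap resample of the
observed rows so that parameter uncertainty propagates (approximate
proper imputation).  A multivariate-normal-on-indicators alternative
(fit to dummy-coded data, draws rounded back to categories) is provided
as the second classical route.

MAR plausibility is probed the standard way: a school random-intercept
logistic regression of each variable's missingness indicator on the
observed covariates — under MCAR all covariate coefficients are null,
under covariate-driven MAR they recover the amputation mechanism.

Estimates from the m completed datasets are pooled with Rubin's rules,
with the Barnard-Rubin small-sample degrees of freedom and the Monte
Carlo standard error sqrt(B/m) used to judge whether m was sufficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .design import design_matrix
from .glmm import fit_mixed_logit
from .harmonize import CATEGORY_LEVELS, SELECTION_COVARIATES
from .synthetic import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "AmputationSpec", "ImputationSet", "PooledEstimate",
    "amputate", "missingness_diagnostic", "impute",
    "pool_rubin", "monte_carlo_error_check",
]


# ---------------------------------------------------------------------------
# amputation (test harness for the MAR pipeline)

@dataclass
class AmputationSpec:
    """Missingness mechanism for one variable.

    ``predictors`` maps observed covariates to per-level log-odds shifts
    of being missing (MAR); empty means MCAR.  The intercept is solved
    so the realized marginal missingness rate matches ``rate`` in
    expectation.  Mechanisms referencing the variable's own value (MNAR)
    are rejected.
    """

    variable: str
    rate: float
    predictors: dict = field(default_factory=dict)


def amputate(records: pd.DataFrame, specs: list[AmputationSpec], seed: int = 0) -> pd.DataFrame:
    """Impose missingness on a complete table; the input is untouched."""
    out = records.copy()
    rng = stage_rng(seed, "amputation")
    for k, spec in enumerate(specs):
        if spec.variable in spec.predictors:
            raise ValueError(f"{spec.variable!r} drives its own missingness: MNAR not supported")
        if not 0.0 <= spec.rate < 1.0:
            raise ValueError("missingness rate must be in [0, 1)")
        if spec.rate == 0.0:
            continue
        shift = np.zeros(len(out))
        for var, effects in spec.predictors.items():
            for level, b in effects.items():
                shift += b * (out[var] == level).to_numpy(dtype=float)

        def realized(alpha):
            return float(np.mean(expit(alpha + shift))) - spec.rate

        alpha = optimize.brentq(realized, -30.0, 30.0, xtol=1e-12)
        miss = rng.random(len(out)) < expit(alpha + shift)
        out.loc[miss, spec.variable] = np.nan
        logger.info("amputate: %s at realized rate %.3f (target %.3f)",
                    spec.variable, miss.mean(), spec.rate)
    return out


# ---------------------------------------------------------------------------
# MAR diagnostic

def missingness_diagnostic(
    records: pd.DataFrame,
    variable: str,
    covariates: list[str] | None = None,
    n_quad: int = 15,
) -> dict:
    """Regress the missingness indicator of ``variable`` on observed covariates.

    Returns the coefficient table of a school random-intercept logistic
    fit; covariate coefficients distinguishable from zero indicate the
    missingness is predictable from observed data (consistent with MAR
    rather than MCAR).
    """
    ind = records[variable].isna().to_numpy()
    if not ind.any():
        raise ValueError(f"{variable!r} is fully observed: nothing to diagnose")
    if ind.all():
        raise ValueError(f"{variable!r} is fully missing: diagnostic undefined")
    covariates = covariates if covariates is not None else [
        c for c in SELECTION_COVARIATES if c != variable
    ]
    usable = records[covariates].notna().all(axis=1).to_numpy()
    if usable.sum() < len(records):
        logger.info("missingness_diagnostic: %d rows dropped for missing predictors",
                    int(len(records) - usable.sum()))
    sub = records.loc[usable]
    X, names = design_matrix(sub, covariates)
    fit = fit_mixed_logit(X, ind[usable].astype(float), groups=sub["school_id"].to_numpy(),
                          names=names, n_quad=n_quad, raise_on_separation=False)
    se = fit.bse("model")
    table = pd.DataFrame({"coef": fit.params, "se": se, "z": fit.params / se}, index=fit.names)
    return {
        "variable": variable,
        "n": int(fit.n),
        "n_missing": int(ind[usable].sum()),
        "sigma_u": fit.sigma_u,
        "coefficients": table,
        "converged": fit.converged,
    }


# ---------------------------------------------------------------------------
# multiple imputation

@dataclass
class ImputationSet:
    """m completed copies of one dataset."""

    m: int
    completed_datasets: list[pd.DataFrame]
    variables: list[str]
    seed: int
    method: str

    def __post_init__(self):
        assert len(self.completed_datasets) == self.m


def _default_impute_variables(records: pd.DataFrame) -> list[str]:
    out = [v for v in SELECTION_COVARIATES if records[v].isna().any()]
    if (records["source"] == "trial").all() and records["outcome_weekly"].isna().any():
        out.append("outcome_weekly")
    return out


def _levels_of(var: str) -> list:
    if var == "outcome_weekly":
        return [0.0, 1.0]
    return CATEGORY_LEVELS[var]


def impute(
    records: pd.DataFrame,
    variables: list[str] | None = None,
    m: int = 20,
    seed: int = 0,
    method: str = "chained_equations",
    predictors: list[str] | None = None,
    cycles: int = 10,
) -> ImputationSet:
    """Multiply impute missing categorical values.

    Trial and survey datasets are imputed separately (call once per
    dataset).  ``predictors`` defaults to the selection-model covariate
    set; the variable being imputed is always excluded from its own
    predictor list.  With no missing values all m completed datasets
    equal the input.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    variables = list(variables) if variables is not None else _default_impute_variables(records)
    for v in variables:
        if records[v].notna().sum() == 0:
            raise ValueError(f"{v!r} has no observed values to learn from")
    predictors = list(predictors) if predictors is not None else list(SELECTION_COVARIATES)

    if method == "chained_equations":
        draw = _mice_one
    elif method == "multivariate_normal":
        draw = _mvn_one
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    # one incomplete variable needs a single pass: its predictors are
    # already complete, so further cycles cannot change the conditionals
    n_incomplete = sum(records[v].isna().any() for v in variables)
    eff_cycles = 1 if n_incomplete <= 1 else cycles
    completed = []
    for j in range(m):
        rng = stage_rng(seed, "imputation", j)
        completed.append(draw(records, variables, predictors, eff_cycles, rng))
    obs_mask = records[variables].notna()
    for df in completed:
        assert not df[variables].isna().any().any(), "imputed dataset still has missing values"
        for v in variables:
            same = df.loc[obs_mask[v], v] == records.loc[obs_mask[v], v]
            assert same.all(), "imputation altered an observed cell"
    return ImputationSet(m=m, completed_datasets=completed, variables=variables,
                         seed=seed, method=method)


def _fit_conditional(sub: pd.DataFrame, var: str, preds: list[str], rng):
    """Multinomial-logistic conditional fitted on a bootstrap resample."""
    from sklearn.linear_model import LogisticRegression

    boot = rng.integers(0, len(sub), len(sub))
    fit_df = sub.iloc[boot]
    levels = [l for l in _levels_of(var) if (fit_df[var] == l).any()]
    if len(levels) < 2:
        return None, levels  # bootstrap collapsed to one level
    Xf, _ = design_matrix(fit_df, preds, add_intercept=False, drop_constant=False)
    yf = pd.Categorical(fit_df[var], categories=levels).codes
    model = LogisticRegression(max_iter=500, C=10.0)
    model.fit(Xf, yf)
    return model, levels


def _mice_one(records, variables, predictors, cycles, rng) -> pd.DataFrame:
    df = records.copy()
    miss = {v: df[v].isna().to_numpy() for v in variables}
    # initialize from observed marginals
    for v in variables:
        obs = df[v].dropna()
        if miss[v].any():
            df.loc[miss[v], v] = rng.choice(obs.to_numpy(), size=int(miss[v].sum()))
    n_cycles = cycles if any(mk.any() for mk in miss.values()) else 0
    for _ in range(n_cycles):
        for v in variables:
            if not miss[v].any():
                continue
            preds = [p for p in predictors if p != v]
            model, levels = _fit_conditional(df, v, preds, rng)
            if model is None:
                df.loc[miss[v], v] = levels[0]
                continue
            Xm, _ = design_matrix(df.loc[miss[v]], preds, add_intercept=False, drop_constant=False)
            probs = model.predict_proba(Xm)
            cum = probs.cumsum(axis=1)
            u = rng.random(len(Xm))[:, None]
            codes = (u > cum).sum(axis=1)
            df.loc[miss[v], v] = [levels[c] for c in codes]
    return df


def _indicator_block(df: pd.DataFrame, var: str) -> tuple[np.ndarray, list]:
    levels = _levels_of(var)
    mat = np.column_stack([(df[var] == l).to_numpy(dtype=float) for l in levels[1:]])
    mat[df[var].isna().to_numpy()] = np.nan
    return mat, levels


def _mvn_one(records, variables, predictors, cycles, rng) -> pd.DataFrame:
    """Joint-normal imputation on the dummy-coded table, rounded back."""
    del cycles
    df = records.copy()
    cols_by_var, blocks, levels_by_var = {}, [], {}
    allvars = list(dict.fromkeys(variables + [p for p in predictors]))
    start = 0
    for v in allvars:
        mat, levels = _indicator_block(df, v)
        blocks.append(mat)
        cols_by_var[v] = list(range(start, start + mat.shape[1]))
        levels_by_var[v] = levels
        start += mat.shape[1]
    Z = np.column_stack(blocks)
    complete = ~np.isnan(Z).any(axis=1)
    if not complete.any():
        raise ValueError("no complete rows to estimate the joint imputation model")
    boot = rng.choice(np.flatnonzero(complete), size=int(complete.sum()))
    mu = Z[boot].mean(axis=0)
    cov = np.cov(Z[boot], rowvar=False) + 1e-8 * np.eye(Z.shape[1])

    for i in np.flatnonzero(~complete):
        row = Z[i]
        mis = np.isnan(row)
        obs = ~mis
        c_oo = cov[np.ix_(obs, obs)]
        c_mo = cov[np.ix_(mis, obs)]
        sol = np.linalg.solve(c_oo, row[obs] - mu[obs])
        cond_mu = mu[mis] + c_mo @ sol
        cond_cov = cov[np.ix_(mis, mis)] - c_mo @ np.linalg.solve(c_oo, c_mo.T)
        draw = rng.multivariate_normal(cond_mu, cond_cov, method="svd")
        Z[i, mis] = draw
    # round back to the nearest category per variable
    for v in variables:
        mask = df[v].isna().to_numpy()
        if not mask.any():
            continue
        levels = levels_by_var[v]
        block = Z[np.ix_(np.flatnonzero(mask), cols_by_var[v])]
        candidates = np.vstack([np.zeros(len(levels) - 1), np.eye(len(levels) - 1)])
        d2 = ((block[:, None, :] - candidates[None, :, :]) ** 2).sum(axis=2)
        choice = d2.argmin(axis=1)
        df.loc[mask, v] = [levels[c] for c in choice]
    return df


# ---------------------------------------------------------------------------
# Rubin's rules

@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    qbar: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    mcse: float
    m: int

    def __post_init__(self):
        assert self.total_var >= self.within_var - 1e-12, "T must dominate W"


def pool_rubin(estimates, variances, nu_com: float | None = None) -> PooledEstimate:
    """Pool estimates across imputations.

    qbar = mean estimate, W = mean within-imputation variance, B =
    between-imputation variance, T = W + (1 + 1/m) B.  Degrees of
    freedom follow Barnard-Rubin when a complete-data ``nu_com`` is
    supplied, otherwise the classical large-sample formula.  The Monte
    Carlo SE of qbar due to finite m is sqrt(B/m).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    mm = len(q)
    if mm < 2:
        raise ValueError("pooling needs at least 2 imputations")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / mm) * B
    if B == 0.0:
        df = float("inf")
    else:
        r = (1.0 + 1.0 / mm) * B / W
        df_large = (mm - 1) * (1.0 + 1.0 / r) ** 2
        if nu_com is None or not np.isfinite(nu_com):
            df = df_large
        else:
            gamma = (1.0 + 1.0 / mm) * B / T
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - gamma)
            df = 1.0 / (1.0 / df_large + 1.0 / nu_obs)
    mcse = float(np.sqrt(B / mm))
    return PooledEstimate(qbar=qbar, within_var=W, between_var=B,
                          total_var=float(T), df=df, mcse=mcse, m=mm)


def monte_carlo_error_check(pooled: PooledEstimate, threshold: float = 0.1) -> dict:
    """Is m large enough?  Flags mcse exceeding 10% of the total SE."""
    total_se = float(np.sqrt(pooled.total_var))
    ratio = pooled.mcse / total_se if total_se > 0 else 0.0
    flag = ratio > threshold
    if flag:
        logger.warning("Monte Carlo error %.3g is %.0f%% of total SE: consider more imputations",
                       pooled.mcse, 100 * ratio)
    return {"mcse": pooled.mcse, "total_se": total_se, "ratio": ratio,
            "m": pooled.m, "flag_more_imputations_needed": flag}
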