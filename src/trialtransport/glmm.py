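"""Random-intercept logistic regression by maximum likelihood.

The workhorse model of the whole pipeline: a logistic regression with a
normal random intercept per cluster (school),

    logit P(Y_ij = 1 | x_ij, u_j) = x_ij' beta + u_j,   u_j ~ N(0, sigma_u^2).

The marginal likelihood integrates u_j out with Gauss-Hermite quadrature;
gradients are analytic.  Per-row weights enter as exponents inside the
cluster integrand (survey-weighted pseudo-likelihood), so integer weights
are exactly equivalent to row replication and unit weights recover the
ordinary mixed-model fit.  Per-cluster score vectors are retained, which
makes the cluster-robust sandwich covariance essentially free.

Fits with ``groups=None`` (or a single cluster) reduce to plain logistic
regression with ``sigma_u`` fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit, logsumexp

__all__ = ["MixedLogitFit", "SeparationError", "fit_mixed_logit", "check_separation"]

_SIGMA_MAX = 6.0


class SeparationError(RuntimeError):
    """A covariate level perfectly predicts the outcome (quasi-separation).

    Raised loudly instead of silently regularizing: in a selection model
    this is a positivity failure, not a numerical nuisance.
    """


def check_separation(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> list[str]:
    """Return design columns whose support perfectly predicts ``y``.

    Checks every non-constant binary (0/1) column: if the outcome is
    constant on the column's on-support (or off-support), the MLE for
    that coefficient is infinite.
    """
    names = names or [f"x{j}" for j in range(X.shape[1])]
    flagged = []
    y = np.asarray(y)
    if y.min() == y.max():
        return ["(outcome constant)"]
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if len(uniq) != 2 or set(uniq) != {0.0, 1.0}:
            continue
        on = y[col == 1.0]
        off = y[col == 0.0]
        if len(on) and on.min() == on.max() and not (len(off) and off.min() == off.max() and off[0] == on[0]):
            flagged.append(names[j])
        elif len(off) and off.min() == off.max():
            flagged.append(names[j])
    return flagged


@dataclass
class MixedLogitFit:
    """Fitted random-intercept logistic model."""

    params: np.ndarray                # fixed-effect coefficients
    sigma_u: float                    # random-intercept SD (0 = no clustering)
    names: list[str]
    cov_model: np.ndarray             # inverse observed information, fixed effects
    cov_cluster: np.ndarray | None    # cluster-robust sandwich, fixed effects
    converged: bool
    loglike: float
    n: int
    n_groups: int
    n_quad: int
    weighted: bool
    cluster_scores: np.ndarray | None = field(default=None, repr=False)
    group_labels: np.ndarray | None = field(default=None, repr=False)
    aliased: list[str] = field(default_factory=list)   # collinear columns dropped

    def bse(self, cov_type: str = "model") -> np.ndarray:
        cov = self.cov_cluster if cov_type == "cluster" else self.cov_model
        if cov is None:
            raise ValueError("cluster covariance unavailable (no grouping)")
        return np.sqrt(np.diag(cov))

    def predict_marginal(self, X: np.ndarray) -> np.ndarray:
        """P(Y=1 | x) averaged over the random-intercept distribution."""
        return marginal_prob(np.asarray(X, float), self.params, self.sigma_u, self.n_quad)

    def predict_conditional(self, X: np.ndarray, u: np.ndarray | float) -> np.ndarray:
        """P(Y=1 | x, u) at given cluster effect(s) ``u``."""
        return expit(np.asarray(X, float) @ self.params + u)


def marginal_prob(X: np.ndarray, beta: np.ndarray, sigma_u: float, n_quad: int = 25) -> np.ndarray:
    """Marginal success probability, integrating the random intercept out."""
    lp = X @ beta
    if sigma_u <= 0:
        return expit(lp)
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    a = wts / np.sqrt(np.pi)
    return expit(lp[:, None] + np.sqrt(2.0) * sigma_u * nodes[None, :]) @ a


def _prepare_groups(groups: np.ndarray):
    labels, inv = np.unique(groups, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    inv_sorted = inv[order]
    starts = np.flatnonzero(np.r_[1, np.diff(inv_sorted)])
    return order, starts, labels, inv


class _MixedLogitObjective:
    """Negative weighted marginal log-likelihood with analytic gradient."""

    def __init__(self, X, y, w, starts, n_quad):
        self.X, self.y, self.w = X, y, w
        self.starts = starts
        nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
        self.nodes = np.sqrt(2.0) * nodes          # u = sigma * nodes
        self.log_a = np.log(wts) - 0.5 * np.log(np.pi)
        self.p = X.shape[1]

    def _pieces(self, theta):
        beta, sigma = theta[:-1], theta[-1]
        lp = self.X @ beta
        eta = lp[:, None] + sigma * self.nodes[None, :]          # (n, K)
        ll = self.w[:, None] * (self.y[:, None] * log_expit(eta)
                                + (1.0 - self.y)[:, None] * log_expit(-eta))
        cl = np.add.reduceat(ll, self.starts, axis=0)            # (J, K)
        lse = logsumexp(cl + self.log_a[None, :], axis=1)        # (J,)
        c = np.exp(cl + self.log_a[None, :] - lse[:, None])      # softmax weights
        resid = self.w[:, None] * (self.y[:, None] - expit(eta))  # (n, K)
        return lse, c, resid

    def cluster_loglik(self, theta):
        return self._pieces(theta)[0]

    def value_grad_scores(self, theta):
        lse, c, resid = self._pieces(theta)
        J, K = c.shape
        scores = np.empty((J, self.p + 1))
        for d in range(self.p):
            Gd = np.add.reduceat(resid * self.X[:, d][:, None], self.starts, axis=0)
            scores[:, d] = np.sum(c * Gd, axis=1)
        Gs = np.add.reduceat(resid, self.starts, axis=0) * self.nodes[None, :]
        scores[:, self.p] = np.sum(c * Gs, axis=1)
        return float(np.sum(lse)), scores.sum(axis=0), scores

    def neg_value_grad(self, theta):
        val, grad, _ = self.value_grad_scores(theta)
        return -val, -grad


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Alias exactly collinear design columns (pivoted-QR rank detection).

    Deterministic relationships between categoricals (e.g. never-smokers
    always reporting 'never' for age at first cigarette) make full-level
    dummy designs rank deficient; the aliased columns get no coefficient,
    exactly as R reports NA for aliased terms.
    """
    if X.shape[1] == 0:
        return X, names, []
    from scipy import linalg

    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(diag[0], 1e-300)))
    if rank == X.shape[1]:
        return X, names, []
    keep = sorted(piv[:rank])
    aliased = [names[j] for j in sorted(piv[rank:])]
    return X[:, keep], [names[j] for j in keep], aliased


def _plain_logit(X, y, w, names, raise_on_separation=True):
    """Plain (fixed-effects only) weighted logistic fit via IRLS."""
    if raise_on_separation:
        sep = check_separation(X, y, names)
        if sep:
            raise SeparationError(f"perfect separation on: {sep}")
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(maxiter=200)
    return res


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
    n_quad: int = 15,
    start: np.ndarray | None = None,
    raise_on_separation: bool = True,
) -> MixedLogitFit:
    """Fit the random-intercept logistic model by Gauss-Hermite ML.

    Parameters
    ----------
    X : (n, p) design matrix including an intercept column.
    y : binary outcome.
    groups : cluster labels; ``None`` (or a single cluster) fixes
        ``sigma_u = 0`` and falls back to plain logistic regression.
    weights : per-row pseudo-likelihood weights (default 1).  Integer
        weights reproduce the fit on row-replicated data exactly.
    n_quad : Gauss-Hermite node count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    X, names, aliased = _drop_collinear(X, names)
    p = X.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    weighted = weights is not None and not np.allclose(w, 1.0)

    n_groups = 0 if groups is None else len(np.unique(groups))
    if groups is None or n_groups < 2:
        res = _plain_logit(X, y, w, names, raise_on_separation)
        return MixedLogitFit(
            params=np.asarray(res.params, float), sigma_u=0.0, names=names,
            cov_model=np.asarray(res.cov_params(), float), cov_cluster=None,
            converged=bool(res.converged), loglike=float(res.llf), n=n,
            n_groups=n_groups, n_quad=n_quad, weighted=weighted, aliased=aliased,
        )

    if raise_on_separation:
        sep = check_separation(X, y, names)
        if sep:
            raise SeparationError(f"perfect separation on: {sep}")

    order, starts, labels, inv = _prepare_groups(np.asarray(groups))
    Xs, ys, ws = X[order], y[order], w[order]
    obj = _MixedLogitObjective(Xs, ys, ws, starts, n_quad)

    if start is None:
        res0 = _plain_logit(X, y, w, names, raise_on_separation=False)
        theta0 = np.r_[np.asarray(res0.params, float), 0.3]
    else:
        theta0 = np.asarray(start, float)

    bounds = [(None, None)] * p + [(0.0, _SIGMA_MAX)]
    opt = optimize.minimize(
        obj.neg_value_grad, theta0, jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = opt.x
    loglike, _, scores = obj.value_grad_scores(theta)

    # observed information by central differences of the analytic gradient
    hess = _numerical_hessian(obj, theta)
    cov_full = _safe_inverse(hess)
    J = len(starts)
    meat = scores.T @ scores
    bread = cov_full
    sandwich = bread @ meat @ bread * (J / max(J - 1, 1))

    return MixedLogitFit(
        params=theta[:p], sigma_u=float(theta[p]), names=names,
        cov_model=cov_full[:p, :p], cov_cluster=sandwich[:p, :p],
        converged=bool(opt.success), loglike=loglike, n=n,
        n_groups=n_groups, n_quad=n_quad, weighted=weighted,
        cluster_scores=scores, group_labels=labels, aliased=aliased,
    )


def _numerical_hessian(obj, theta, eps=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        h = eps * max(1.0, abs(theta[j]))
        tp[j] += h
        tm[j] -= h
        if tm[j] < 0 and j == k - 1:   # sigma bound
            tm[j] = 0.0
            h = (tp[j] - tm[j]) / 2.0
        _, gp, _ = obj.value_grad_scores(tp)
        _, gm, _ = obj.value_grad_scores(tm)
        H[j] = -(gp - gm) / (tp[j] - tm[j])
    return 0.5 * (H + H.T)


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def empirical_bayes_modes(fit: MixedLogitFit, X, y, groups, weights=None, n_iter=25) -> dict:
    """Posterior modes of the cluster random intercepts.

    Newton iterations on the per-cluster posterior
    ``sum_i w_i log f(y_i | u) - u^2 / (2 sigma_u^2)``.
    """
    if fit.sigma_u <= 0:
        return {g: 0.0 for g in np.unique(groups)}
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    order, starts, labels, inv = _prepare_groups(np.asarray(groups))
    lp = (X @ fit.params)[order]
    ys, ws = y[order], w[order]
    idx = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, len(ys)]))
    u = np.zeros(len(starts))
    s2 = fit.sigma_u ** 2
    for _ in range(n_iter):
        eta = lp + u[idx]
        pr = expit(eta)
        g = np.bincount(idx, weights=ws * (ys - pr), minlength=len(starts)) - u / s2
        h = -np.bincount(idx, weights=ws * pr * (1 - pr), minlength=len(starts)) - 1.0 / s2
        step = g / h
        u -= np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return dict(zip(labels, u))
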