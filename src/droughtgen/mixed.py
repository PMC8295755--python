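"""Random-intercept mixed models for repeated drought-response records.

Two designs cover everything the pipeline needs:

* a single random intercept (individual trees as groups), used for
  provenance-level repeatability and, with fixed-effect design matrices and
  maximum likelihood, for the stepwise model comparisons;
* tree intercepts nested in provenance intercepts, used for species-level
  repeatability where provenance variance must be separated from the
  among-tree variance.

Variance components are estimated by direct maximization of the profiled
restricted (or full) log-likelihood over variance ratios; the grouped
structure gives closed-form determinants and inverses (Sherman-Morrison per
group for the single-intercept model, small dense solves per provenance for
the nested model), so fits cost microseconds and the profile can be
maximized to high precision.  Negative components are truncated at zero and
flagged as boundary estimates.  The asymptotic covariance of the components
comes from the finite-difference observed-information matrix of the
restricted log-likelihood at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

__all__ = ["RandomInterceptFit", "NestedFit", "fit_random_intercept", "fit_nested"]

_BOUNDARY_RATIO = 1e-8  # lambda below this is treated as a zero component
_LOG_LAM_LO, _LOG_LAM_HI = -16.0, 10.0


@dataclass
class RandomInterceptFit:
    """REML or ML fit of y = X beta + u_group + e."""

    method: str
    beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    n_params: int
    aic: float
    n_obs: int
    n_groups: int
    boundary: bool
    cov_components: np.ndarray | None  # 2x2, order (group, resid)


@dataclass
class NestedFit:
    """REML fit of y = X beta + u_prov + u_tree + e (trees nested in provenances)."""

    method: str
    beta: np.ndarray
    sigma2_tree: float
    sigma2_prov: float
    sigma2_resid: float
    loglik: float
    n_obs: int
    n_trees: int
    n_provenances: int
    boundary: bool
    cov_components: np.ndarray | None  # 3x3, order (tree, prov, resid)


def _prepare(y, groups, X):
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if X is None:
        X = np.ones((len(y), 1))
    X = np.asarray(X, dtype=float)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, starts, sizes = np.unique(groups, return_index=True, return_counts=True)
    return y, X, starts, sizes


def _profile_stats(y, X, starts, sizes):
    """Sufficient statistics for the profiled likelihood."""
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S = np.add.reduceat(X, starts, axis=0)  # group sums of rows of X
    t = np.add.reduceat(y, starts)          # group sums of y
    return XtX, Xty, yty, S, t


def _ri_nll(lam, sizes, XtX, Xty, yty, S, t, n, p, method):
    """Negative profiled (restricted) log-likelihood at variance ratio lam."""
    c = lam / (1.0 + sizes * lam)
    XtViX = XtX - (S * c[:, None]).T @ S
    XtViy = Xty - S.T @ (c * t)
    ytViy = yty - float(np.sum(c * t * t))
    try:
        cf = cho_factor(XtViX)
    except np.linalg.LinAlgError:
        return math.inf, None, None
    beta = cho_solve(cf, XtViy)
    rss = ytViy - float(beta @ XtViy)
    if rss <= 0:
        return math.inf, None, None
    logdet_sigma = float(np.sum(np.log1p(sizes * lam)))
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_sigma + n)
    else:
        sigma2 = rss / (n - p)
        # logdet_xvx is on the correlation (Sigma) scale already
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((n - p) * math.log(2 * math.pi * sigma2) + logdet_sigma
                     + logdet_xvx + (n - p))
    return -ll, beta, sigma2


def _ri_rll_variances(theta, sizes, XtX, Xty, yty, S, t, n, p):
    """Unprofiled restricted log-likelihood at variances (a, w)."""
    a, w = theta
    if w <= 0 or a < 0:
        return -math.inf
    d = a / (w + sizes * a)
    XtViX = (XtX - (S * d[:, None]).T @ S) / w
    XtViy = (Xty - S.T @ (d * t)) / w
    ytViy = (yty - float(np.sum(d * t * t))) / w
    try:
        cf = cho_factor(XtViX)
    except np.linalg.LinAlgError:
        return -math.inf
    beta = cho_solve(cf, XtViy)
    rss = ytViy - float(beta @ XtViy)
    logdet_v = float(np.sum((sizes - 1) * math.log(w) + np.log(w + sizes * a)))
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet_v + logdet_xvx + rss)


def _fd_hessian(f, x0, rel_step=1e-4):
    """Central finite-difference Hessian of scalar f at x0."""
    x0 = np.asarray(x0, dtype=float)
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-9)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f(x0) + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _component_cov(neg_rll, estimates):
    """Inverse observed information; None when it is not positive definite."""
    try:
        H = _fd_hessian(neg_rll, estimates)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    return 0.5 * (cov + cov.T)


def fit_random_intercept(y, groups, X=None, method: str = "REML") -> RandomInterceptFit:
    """Fit a single-random-intercept model by profiled (RE)ML.

    Parameters
    ----------
    y : array of responses.
    groups : array of group labels (one random intercept per label).
    X : fixed-effect design matrix; default a column of ones.
    method : "REML" for variance components, "ML" for likelihood-ratio
        comparisons of fixed effects.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y, X, starts, sizes = _prepare(y, groups, X)
    n, p = len(y), X.shape[1]
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if not np.any(sizes >= 2):
        raise ValueError("need repeated observations within at least one group")
    if n - p < 1:
        raise ValueError("singular design: no residual degrees of freedom")
    XtX, Xty, yty, S, t = _profile_stats(y, X, starts, sizes)
    if p == 1 and np.allclose(X, 1.0):
        # degenerate case: identical repeats within every group make the
        # likelihood unbounded (sigma2_W -> 0); report the boundary directly
        within_ss = yty - float(np.sum(t * t / sizes))
        total_ss = yty - n * float(y.mean()) ** 2
        if within_ss <= 1e-12 * max(total_ss, 1.0):
            means = t / sizes
            return RandomInterceptFit(
                method=method, beta=np.array([float(y.mean())]),
                sigma2_group=float(np.var(means, ddof=1)), sigma2_resid=0.0,
                loglik=math.inf, n_params=p + 2, aic=-math.inf, n_obs=n,
                n_groups=len(sizes), boundary=True, cov_components=None,
            )
    args = (sizes, XtX, Xty, yty, S, t, n, p, method)

    def nll_of_log_lam(u: float) -> float:
        return _ri_nll(math.exp(u), *args)[0]

    # deterministic multi-start: three bounded searches over the log-ratio,
    # plus the boundary lambda = 0
    brackets = [(_LOG_LAM_LO, -2.0), (-4.0, 4.0), (2.0, _LOG_LAM_HI)]
    best_u, best_val = None, math.inf
    for lo, hi in brackets:
        r = minimize_scalar(nll_of_log_lam, bounds=(lo, hi), method="bounded",
                            options={"xatol": 1e-12})
        if r.fun < best_val:
            best_u, best_val = float(r.x), float(r.fun)
    nll0 = _ri_nll(0.0, *args)[0]
    if nll0 <= best_val:
        lam = 0.0
    else:
        lam = math.exp(best_u)
    nll, beta, sigma2 = _ri_nll(lam, *args)
    if beta is None:
        raise RuntimeError("mixed-model fit failed: singular profiled system")
    boundary = lam <= _BOUNDARY_RATIO
    if boundary:
        lam = 0.0
        nll, beta, sigma2 = _ri_nll(lam, *args)
    sigma2_group = lam * sigma2
    loglik = -nll
    n_params = p + 2
    cov = None
    if method == "REML" and not boundary:
        cov = _component_cov(
            lambda th: -_ri_rll_variances(th, sizes, XtX, Xty, yty, S, t, n, p),
            np.array([sigma2_group, sigma2]),
        )
    return RandomInterceptFit(
        method=method, beta=beta, sigma2_group=float(sigma2_group), sigma2_resid=float(sigma2),
        loglik=float(loglik), n_params=n_params, aic=2 * n_params - 2 * loglik,
        n_obs=n, n_groups=len(sizes), boundary=boundary, cov_components=cov,
    )


# ---------------------------------------------------------------------------
# Nested model: provenance + tree random intercepts
# ---------------------------------------------------------------------------

def _nested_blocks(y, prov, tree, X):
    y = np.asarray(y, dtype=float)
    prov = np.asarray(prov)
    tree = np.asarray(tree)
    if X is None:
        X = np.ones((len(y), 1))
    X = np.asarray(X, dtype=float)
    order = np.lexsort((tree, prov))
    y, X, prov, tree = y[order], X[order], prov[order], tree[order]
    blocks = []
    n_trees = len(np.unique(tree))
    for pv in np.unique(prov):
        m = prov == pv
        yj, Xj, tj = y[m], X[m], tree[m]
        _, codes = np.unique(tj, return_inverse=True)
        Z = np.zeros((len(yj), codes.max() + 1))
        Z[np.arange(len(yj)), codes] = 1.0
        blocks.append((yj, Xj, Z @ Z.T, np.ones((len(yj), len(yj)))))
    return blocks, X.shape[1], len(y), n_trees


def _nested_nll(lam_tree, lam_prov, blocks, n, p, method="REML"):
    """Profiled REML/ML negative log-likelihood at the two variance ratios."""
    XtViX = 0.0
    XtViy = 0.0
    ytViy = 0.0
    logdet_sigma = 0.0
    for yj, Xj, ZZt, J in blocks:
        Sig = np.eye(len(yj)) + lam_tree * ZZt + lam_prov * J
        try:
            cf = cho_factor(Sig)
        except np.linalg.LinAlgError:
            return math.inf, None, None
        logdet_sigma += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        SiX = cho_solve(cf, Xj)
        Siy = cho_solve(cf, yj)
        XtViX = XtViX + Xj.T @ SiX
        XtViy = XtViy + Xj.T @ Siy
        ytViy += float(yj @ Siy)
    try:
        cf2 = cho_factor(XtViX)
    except np.linalg.LinAlgError:
        return math.inf, None, None
    beta = cho_solve(cf2, XtViy)
    rss = ytViy - float(beta @ XtViy)
    if rss <= 0:
        return math.inf, None, None
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_sigma + n)
    else:
        sigma2 = rss / (n - p)
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf2[0]))))
        ll = -0.5 * ((n - p) * math.log(2 * math.pi * sigma2) + logdet_sigma
                     + logdet_xvx + (n - p))
    return -ll, beta, sigma2


def _nested_rll_variances(theta, blocks, n, p):
    a, pv, w = theta
    if w <= 0 or a < 0 or pv < 0:
        return -math.inf
    XtViX = 0.0
    XtViy = 0.0
    ytViy = 0.0
    logdet_v = 0.0
    for yj, Xj, ZZt, J in blocks:
        V = w * np.eye(len(yj)) + a * ZZt + pv * J
        try:
            cf = cho_factor(V)
        except np.linalg.LinAlgError:
            return -math.inf
        logdet_v += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ViX = cho_solve(cf, Xj)
        Viy = cho_solve(cf, yj)
        XtViX = XtViX + Xj.T @ ViX
        XtViy = XtViy + Xj.T @ Viy
        ytViy += float(yj @ Viy)
    try:
        cf2 = cho_factor(XtViX)
    except np.linalg.LinAlgError:
        return -math.inf
    beta = cho_solve(cf2, XtViy)
    rss = ytViy - float(beta @ XtViy)
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf2[0]))))
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet_v + logdet_xvx + rss)


def fit_nested(y, provenances, trees, X=None, method: str = "REML") -> NestedFit:
    """Fit provenance + tree random intercepts (trees nested in provenances)."""
    blocks, p, n, n_trees = _nested_blocks(y, provenances, trees, X)
    if len(blocks) < 2:
        raise ValueError("need at least 2 provenances; use the single-intercept model otherwise")

    def nll(v):
        return _nested_nll(max(v[0], 0.0), max(v[1], 0.0), blocks, n, p, method)[0]

    starts = [(0.1, 0.1), (1.0, 0.5), (0.01, 0.01)]
    best = None
    for s in starts:
        r = minimize(nll, np.array(s), method="L-BFGS-B",
                     bounds=[(0.0, 1e4), (0.0, 1e4)],
                     options={"ftol": 1e-14, "gtol": 1e-10})
        if best is None or r.fun < best.fun:
            best = r
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("nested mixed-model fit did not converge")
    lam_tree, lam_prov = (max(float(v), 0.0) for v in best.x)
    b_tree = lam_tree <= _BOUNDARY_RATIO
    b_prov = lam_prov <= _BOUNDARY_RATIO
    lam_tree = 0.0 if b_tree else lam_tree
    lam_prov = 0.0 if b_prov else lam_prov
    nllv, beta, sigma2 = _nested_nll(lam_tree, lam_prov, blocks, n, p, method)
    if beta is None:
        raise RuntimeError("nested mixed-model fit failed at the optimum")
    a, pv = lam_tree * sigma2, lam_prov * sigma2
    cov = None
    if method == "REML" and not b_tree:
        cov = _component_cov(lambda th: -_nested_rll_variances(th, blocks, n, p),
                             np.array([a, pv, sigma2]))
    return NestedFit(
        method=method, beta=beta, sigma2_tree=float(a), sigma2_prov=float(pv),
        sigma2_resid=float(sigma2), loglik=float(-nllv), n_obs=n, n_trees=n_trees,
        n_provenances=len(blocks), boundary=b_tree or b_prov, cov_components=cov,
    )
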