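"""Fast REML for the single-random-intercept linear mixed model.

The mass-univariate maps need tens of thousands of fits of the same small
model, y = X beta + u_group + eps with u_group ~ N(0, sigma_u^2) and
eps ~ N(0, sigma_e^2).  For that model the REML criterion can be profiled
down to a one-dimensional optimization over the variance ratio
tau = sigma_u^2 / sigma_e^2, with closed-form GLS for beta at each candidate
(block-diagonal Woodbury identities per group).  A statsmodels MixedLM
backend is kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DesignMatrixError

__all__ = ["LMMFit", "fit_random_intercept"]


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray  # two-sided Wald (normal) p-values
    sigma2_e: float
    sigma2_u: float
    converged: bool
    method: str = "profile-reml"


def _gls_pieces(y, X, group_sums_idx, tau):
    """X'V^-1 X, X'V^-1 y, and log|V| for V = I + tau * Z Z' (unit sigma_e)."""
    groups, counts = group_sums_idx
    XtX = X.T @ X
    Xty = X.T @ y
    logdet = 0.0
    # subtract tau/(1+tau n_g) * s_g s_g' per group
    for g_rows, n_g in zip(groups, counts):
        w = tau / (1.0 + tau * n_g)
        s = X[g_rows].sum(axis=0)
        t = y[g_rows].sum()
        XtX -= w * np.outer(s, s)
        Xty -= w * s * t
        logdet += np.log1p(tau * n_g)
    return XtX, Xty, logdet


def _quad_form_resid(y, X, beta, group_sums_idx, tau):
    """r' V^-1 r for r = y - X beta."""
    groups, counts = group_sums_idx
    r = y - X @ beta
    q = float(r @ r)
    for g_rows, n_g in zip(groups, counts):
        w = tau / (1.0 + tau * n_g)
        q -= w * float(r[g_rows].sum()) ** 2
    return q, r


def _neg2_reml(log_tau, y, X, gidx, n, p):
    tau = np.exp(log_tau)
    XtX, Xty, logdetV = _gls_pieces(y, X, gidx, tau)
    try:
        beta = np.linalg.solve(XtX, Xty)
        sign, logdetX = np.linalg.slogdet(XtX)
        if sign <= 0:
            return np.inf
    except np.linalg.LinAlgError:
        return np.inf
    q, _ = _quad_form_resid(y, X, beta, gidx, tau)
    if q <= 0:
        return np.inf
    return logdetV + logdetX + (n - p) * np.log(q)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    method: str = "profile",
) -> LMMFit:
    """REML fit of a linear model with one random intercept.

    ``method="profile"`` (default) optimizes the profiled REML criterion over
    log variance ratio; ``method="mixedlm"`` delegates to statsmodels (slow,
    used as an oracle).  With a single group level, or when the variance
    ratio hits the zero boundary, the result equals ordinary least squares.
    Wald p-values use the normal reference distribution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise DesignMatrixError("need at least 2 more observations than parameters")
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the caller
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            if np.linalg.norm(X[:, j] - others @ proj) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(j)
        raise DesignMatrixError(f"rank-deficient design; collinear columns {bad}")

    codes, _ = _group_codes(groups)
    n_groups = codes.max() + 1
    gidx = _group_index(codes, n_groups)

    if method == "mixedlm":
        return _fit_mixedlm(y, X, codes)
    if n_groups < 2:
        return _ols_fit(y, X)

    obj = lambda lt: _neg2_reml(lt, y, X, gidx, n, p)
    res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    tau = float(np.exp(res.x))
    # boundary check: compare against tau -> 0 (OLS)
    if obj(np.log(1e-12)) <= res.fun + 1e-10:
        fit = _ols_fit(y, X)
        fit.converged = True
        return fit
    XtX, Xty, _ = _gls_pieces(y, X, gidx, tau)
    beta = np.linalg.solve(XtX, Xty)
    q, _ = _quad_form_resid(y, X, beta, gidx, tau)
    sigma2_e = q / (n - p)
    cov = np.linalg.inv(XtX) * sigma2_e
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LMMFit(beta, se, pvals, sigma2_e, tau * sigma2_e, bool(res.success))


def _group_codes(groups):
    levels, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, levels


def _group_index(codes, n_groups):
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.searchsorted(sorted_codes, np.arange(n_groups + 1))
    rows = [order[bounds[g] : bounds[g + 1]] for g in range(n_groups)]
    counts = [len(r) for r in rows]
    return rows, counts


def _ols_fit(y, X) -> LMMFit:
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(r @ r) / (n - p)
    cov = np.linalg.inv(X.T @ X) * sigma2
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    return LMMFit(beta, se, pvals, sigma2, 0.0, True, method="ols-boundary")


def _fit_mixedlm(y, X, codes) -> LMMFit:
    import statsmodels.api as sm

    model = sm.MixedLM(y, X, groups=codes)
    res = model.fit(reml=True, method="lbfgs")
    beta = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    sigma2_u = float(res.cov_re.iloc[0, 0]) if hasattr(res.cov_re, "iloc") else float(res.cov_re[0, 0])
    return LMMFit(beta, se, pvals, float(res.scale), sigma2_u, bool(res.converged), method="mixedlm")
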