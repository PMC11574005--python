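"""TV-L1 structured-sparsity classifiers of disease stage.

Two models share one machinery: a binary logistic regression (Logit-TVL1)
and its ordinal cumulative-logit extension (Ordit) in which a single weight
map w and K-1 ordered thresholds theta_1 < ... < theta_{K-1} model
P(stage <= k | x) = sigmoid(theta_k - w'x).  Both are penalized by
lambda_l1 * ||w||_1 (sparsity) + lambda_tv * TV(w) (spatial cohesion over
mesh edges) and fitted by monotone FISTA with backtracking; the composite
prox is exact (see :mod:`shapestage.tv`).  Hyperparameters are selected by
(nested) stratified cross-validated grid search with training-fold-only
imputation and inverse-frequency class weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ImputationError, LabelError, ParameterError
from .tv import incidence, prox_l1_tv, tv_norm

__all__ = [
    "StructuredLinearModel",
    "CVReport",
    "fit_logit_tvl1",
    "fit_ordit",
    "predict",
    "impute_missing",
    "class_balance_weights",
    "nested_cv",
    "weight_map",
    "default_lambda_grid",
]

logger = logging.getLogger(__name__)


@dataclass
class StructuredLinearModel:
    """Vertex weight map with intercept (binary) or ordered thresholds
    (ordinal), plus its regularization and solver diagnostics."""

    w: np.ndarray
    intercept: float | None  # binary only
    thresholds: np.ndarray | None  # ordinal only, strictly increasing
    K: int
    lambda_l1: float
    lambda_tv: float
    solver_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.K < 2:
            raise ParameterError("K must be >= 2")
        if self.thresholds is not None and np.any(np.diff(self.thresholds) <= 0):
            raise ParameterError("thresholds must be strictly increasing")

    @property
    def is_ordinal(self) -> bool:
        return self.thresholds is not None


@dataclass
class CVReport:
    outer_assignments: np.ndarray  # outer test-fold index per subject
    selected: list[tuple[float, float]]  # (lambda_l1, lambda_tv) per fold
    fold_metrics: list[float]
    metric: str
    seed: int

    @property
    def mean_metric(self) -> float:
        return float(np.mean(self.fold_metrics))


# ---------------------------------------------------------------------------
# losses


def _logistic_loss_grad(params, X, y01, s):
    """Weighted logistic NLL and gradient; params = [b, w...]."""
    b, w = params[0], params[1:]
    z = X @ w + b
    # NLL_i = log(1 + exp(z)) - y*z, weighted
    nll = float(np.sum(s * (np.logaddexp(0.0, z) - y01 * z)))
    g = s * (expit(z) - y01)
    grad = np.concatenate([[g.sum()], X.T @ g])
    return nll, grad


def _ordinal_unpack(params, K):
    """params = [theta1, d_2..d_{K-1}, w...] with softplus increments."""
    theta1 = params[0]
    d = params[1 : K - 1]
    inc = np.logaddexp(0.0, d)  # softplus > 0
    thetas = theta1 + np.concatenate([[0.0], np.cumsum(inc)])
    return thetas, d


def _ordinal_loss_grad(params, X, yk, s, K):
    """Weighted cumulative-logit NLL and gradient.

    yk holds classes 1..K; thresholds are theta_1..theta_{K-1} with
    theta = theta1 + cumsum(softplus(d)) enforcing strict ordering.
    """
    thetas, d = _ordinal_unpack(params, K)
    w = params[K - 1 :]
    z = X @ w
    n = len(z)
    a = np.where(yk < K, thetas[np.minimum(yk, K - 1) - 1] - z, np.inf)
    b = np.where(yk > 1, thetas[np.maximum(yk - 2, 0)] - z, -np.inf)
    sa = expit(a)
    sb = expit(b)
    P = np.clip(sa - sb, 1e-300, None)
    nll = float(np.sum(-s * np.log(P)))
    # derivative pieces: sigma'(x) = sigma(x)(1 - sigma(x)); 0 at +-inf
    da = np.where(np.isfinite(a), sa * (1 - sa), 0.0)
    db = np.where(np.isfinite(b), sb * (1 - sb), 0.0)
    dz = s * (da - db) / P  # dNLL/dz
    grad_w = X.T @ dz
    gtheta = np.zeros(K - 1)
    ia = yk < K  # a used theta_{yk}
    np.add.at(gtheta, yk[ia] - 1, -s[ia] * da[ia] / P[ia])
    ib = yk > 1  # b used theta_{yk-1}
    np.add.at(gtheta, yk[ib] - 2, s[ib] * db[ib] / P[ib])
    g_theta1 = gtheta.sum()
    # d_j feeds thetas j+1..K-1 (0-based: inc[j] enters theta indices >= j+1)
    tail = np.cumsum(gtheta[::-1])[::-1]
    g_d = expit(d) * tail[1:] if K > 2 else np.empty(0)
    return nll, np.concatenate([[g_theta1], g_d, grad_w])


# ---------------------------------------------------------------------------
# monotone FISTA with backtracking


def _mfista(loss_grad, prox_free, x0, max_iter, tol, L0=1.0):
    """Monotone FISTA: smooth loss + penalty handled by ``prox_free``.

    ``prox_free(v, step)`` applies the composite prox to the penalized block
    of v (free parameters pass through).  Returns (x, trace, converged).
    The recorded objective (loss + penalty) is non-increasing by
    construction.
    """
    x = x0.copy()
    yv = x0.copy()
    t = 1.0
    L = L0
    fx, _ = loss_grad(x)
    obj_x = fx + prox_free.penalty(x)
    trace = [obj_x]
    converged = False
    for _ in range(max_iter):
        fy, gy = loss_grad(yv)
        # backtracking on the majorization at y
        for _bt in range(60):
            z = prox_free(yv - gy / L, 1.0 / L)
            fz, _ = loss_grad(z)
            dz = z - yv
            if fz <= fy + gy @ dz + 0.5 * L * float(dz @ dz) + 1e-12:
                break
            L *= 2.0
        obj_z = fz + prox_free.penalty(z)
        if obj_z > obj_x:
            # momentum overshoot: restart from the current best point
            t = 1.0
            yv = x.copy()
            trace.append(obj_x)
            continue
        rel = (obj_x - obj_z) / max(1.0, abs(obj_z))
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        yv = z + ((t - 1.0) / t_new) * (z - x)
        x, obj_x, t = z, obj_z, t_new
        trace.append(obj_x)
        if rel < tol:
            converged = True
            break
    return x, trace, converged


class _ProxFree:
    """Composite prox over the w block; free (unpenalized) block untouched."""

    def __init__(self, n_free, lam_l1, lam_tv, D, edges, gap_tol=1e-7):
        self.n_free = n_free
        self.lam_l1 = lam_l1
        self.lam_tv = lam_tv
        self.D = D
        self.edges = edges
        self.gap_tol = gap_tol

    def __call__(self, v, step):
        out = v.copy()
        # prox_l1_tv's tol is a sup-norm bound; the fixed duality-gap
        # tolerance gap_tol corresponds to sqrt(2 * gap_tol)
        out[self.n_free :] = prox_l1_tv(
            v[self.n_free :],
            step * self.lam_l1,
            step * self.lam_tv,
            self.D,
            tol=float(np.sqrt(2.0 * self.gap_tol)),
            max_iter=5000,
            check=False,
        )
        return out

    def penalty(self, v):
        w = v[self.n_free :]
        return self.lam_l1 * float(np.abs(w).sum()) + self.lam_tv * tv_norm(w, self.edges)


def _check_binary(y):
    classes = np.unique(y)
    if len(classes) != 2:
        raise LabelError(f"need exactly two classes, got {classes}")
    return (np.asarray(y) == classes[1]).astype(float), classes


def fit_logit_tvl1(
    X: np.ndarray,
    y: np.ndarray,
    lambda_l1: float,
    lambda_tv: float,
    edges: np.ndarray,
    class_weights: dict | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    prox_gap: float = 1e-7,
) -> StructuredLinearModel:
    """Binary logistic regression with L1 + graph-TV structured sparsity.

    Minimizes the (class-weighted) logistic loss + lambda_l1*||w||_1
    + lambda_tv*TV(w); the intercept is unpenalized.  The recorded objective
    trace is non-increasing (monotone FISTA).
    """
    X = np.asarray(X, dtype=float)
    y01, classes = _check_binary(y)
    s = np.ones(len(y01))
    if class_weights is not None:
        key = {str(c): v for c, v in class_weights.items()}
        s = np.array([class_weights.get(c, key.get(str(c), 1.0)) for c in np.asarray(y)], dtype=float)
    edges = np.asarray(edges, dtype=np.int64)
    D = incidence(edges, X.shape[1])
    prox = _ProxFree(1, lambda_l1, lambda_tv, D, edges, gap_tol=prox_gap)
    x0 = np.zeros(X.shape[1] + 1)
    loss = lambda p: _logistic_loss_grad(p, X, y01, s)
    params, trace, conv = _mfista(loss, prox, x0, max_iter, tol)
    report = {
        "iterations": len(trace) - 1,
        "objective": trace[-1],
        "converged": conv,
        "objective_trace": trace,
        "classes": list(classes),
    }
    return StructuredLinearModel(
        params[1:], float(params[0]), None, 2, lambda_l1, lambda_tv, report
    )


def fit_ordit(
    X: np.ndarray,
    stages: np.ndarray,
    lambda_l1: float,
    lambda_tv: float,
    edges: np.ndarray,
    class_weights: dict | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    prox_gap: float = 1e-7,
) -> StructuredLinearModel:
    """Ordinal (cumulative-logit) TV-L1 classifier with shared weight map.

    ``stages`` must form a contiguous ordered label set (mapped to 1..K).
    Thresholds are parameterized as theta_1 plus softplus increments, so
    strict ordering holds on every fit.  With K = 2 the model is exactly the
    binary fit under theta_1 = -intercept.
    """
    X = np.asarray(X, dtype=float)
    stages = np.asarray(stages)
    try:
        numeric = stages.astype(float)
    except (TypeError, ValueError) as exc:
        raise LabelError("ordinal stages must be numeric (ordered codes)") from exc
    levels = np.unique(numeric)
    K = len(levels)
    if K < 2:
        raise LabelError("need at least two ordered classes")
    if np.any(levels != np.round(levels)) or np.any(np.diff(levels) != 1):
        raise LabelError(
            f"stage labels {levels.tolist()} do not form a contiguous ordered set"
        )
    yk = np.searchsorted(levels, numeric) + 1  # 1..K
    s = np.ones(len(yk))
    if class_weights is not None:
        key = {str(c): v for c, v in class_weights.items()}
        s = np.array([class_weights.get(c, key.get(str(c), 1.0)) for c in stages], dtype=float)
    edges = np.asarray(edges, dtype=np.int64)
    D = incidence(edges, X.shape[1])
    n_free = K - 1  # theta1 + (K-2) increments
    prox = _ProxFree(n_free, lambda_l1, lambda_tv, D, edges, gap_tol=prox_gap)
    x0 = np.zeros(X.shape[1] + n_free)
    # spread initial thresholds so classes start distinguishable
    x0[0] = -1.0
    loss = lambda p: _ordinal_loss_grad(p, X, yk, s, K)
    params, trace, conv = _mfista(loss, prox, x0, max_iter, tol)
    thetas, _ = _ordinal_unpack(params[: K - 1], K)
    report = {
        "iterations": len(trace) - 1,
        "objective": trace[-1],
        "converged": conv,
        "objective_trace": trace,
        "classes": list(levels),
    }
    return StructuredLinearModel(
        params[K - 1 :], None, thetas, K, lambda_l1, lambda_tv, report
    )


def predict(model: StructuredLinearModel, X: np.ndarray):
    """Scores and class labels.

    Binary: probability sigmoid(w'x + intercept) and the 0.5-threshold
    label (index into the fitted classes).  Ordinal: class probabilities
    from consecutive cumulative differences (they sum to 1) and the argmax
    class 1..K.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.w):
        raise ParameterError(
            f"X has {X.shape[1]} features, model expects {len(model.w)}"
        )
    z = X @ model.w
    if not model.is_ordinal:
        prob = expit(z + model.intercept)
        return prob, (prob >= 0.5).astype(int)
    cum = expit(model.thresholds[None, :] - z[:, None])  # (n, K-1)
    probs = np.diff(np.concatenate([np.zeros((len(z), 1)), cum, np.ones((len(z), 1))], axis=1), axis=1)
    labels = np.argmax(probs, axis=1) + 1
    return probs, labels


def impute_missing(X_train: np.ndarray, X_test: np.ndarray | None = None):
    """Column-mean imputation fitted on the training matrix only."""
    X_train = np.asarray(X_train, dtype=float)
    obs = ~np.isnan(X_train)
    if np.any(obs.sum(axis=0) == 0):
        bad = np.flatnonzero(obs.sum(axis=0) == 0)
        raise ImputationError(f"columns fully missing in training data: {bad.tolist()}")
    means = np.nanmean(X_train, axis=0)
    Xtr = np.where(np.isnan(X_train), means, X_train)
    if X_test is None:
        return Xtr, None
    X_test = np.asarray(X_test, dtype=float)
    Xte = np.where(np.isnan(X_test), means, X_test)
    return Xtr, Xte


def class_balance_weights(y) -> dict:
    """Inverse-frequency weights: n_total / (n_classes * n_c) per class."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n, k = len(y), len(classes)
    return {c: n / (k * nc) for c, nc in zip(classes, counts)}


def default_lambda_grid(n: int = 5, lo: float = 1e-3, hi: float = 10.0):
    """Logarithmic n x n grid of (lambda_l1, lambda_tv) pairs."""
    vals = np.logspace(np.log10(lo), np.log10(hi), n)
    return [(float(a), float(b)) for a in vals for b in vals]


def _score(metric, model, X, y_true):
    classes = np.asarray(model.solver_report["classes"])
    if metric == "roc_auc":
        if model.is_ordinal:
            raise ParameterError("roc_auc is a binary metric")
        scores, _ = predict(model, X)
        y01 = (np.asarray(y_true) == classes[1]).astype(int)
        return float(roc_auc_score(y01, scores))
    if metric == "balanced_f1":
        _, labels = predict(model, X)
        if model.is_ordinal:
            pred = classes[labels - 1]
        else:
            pred = classes[labels]
        return float(f1_score(np.asarray(y_true).astype(float) if model.is_ordinal else y_true, pred, average="macro"))
    raise ParameterError(f"unknown metric {metric!r}")


def _select_lambda(results, rule):
    """Pick (lambda_l1, lambda_tv) from [(lam, fold_scores), ...].

    ``rule="best"`` takes the best mean score, ties toward the larger total
    penalty; ``rule="1se"`` (default elsewhere) takes the largest total
    penalty whose mean score is within one standard error of the best —
    the usual parsimony rule for regularization paths, where CV cannot
    distinguish fits within noise.
    """
    stats = []
    for lam, scores in results:
        scores = np.asarray(scores, dtype=float)
        se = scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0
        stats.append((lam, float(scores.mean()), float(se)))
    best_mean, best_se = max((m, s_) for _, m, s_ in stats)[0], None
    for lam, m, s_ in stats:
        if m == best_mean:
            best_se = s_
            break
    if rule == "best":
        return max(stats, key=lambda t: (t[1], t[0][0] + t[0][1]))[0]
    if rule != "1se":
        raise ParameterError(f"unknown selection rule {rule!r}")
    cutoff = best_mean - best_se
    eligible = [(lam, m) for lam, m, _ in stats if m >= cutoff]
    return max(eligible, key=lambda t: (t[0][0] + t[0][1], t[1]))[0]


def _fit_task(X, y, lam, edges, ordinal, fit_kwargs):
    weights = class_balance_weights(y)
    if ordinal:
        return fit_ordit(X, y, lam[0], lam[1], edges, class_weights=weights, **fit_kwargs)
    return fit_logit_tvl1(X, y, lam[0], lam[1], edges, class_weights=weights, **fit_kwargs)


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[tuple[float, float]],
    edges: np.ndarray,
    outer_k: int = 4,
    inner_k: int = 4,
    metric: str = "roc_auc",
    seed: int = 0,
    ordinal: bool = False,
    fit_kwargs: dict | None = None,
    selection_rule: str = "1se",
) -> CVReport:
    """Nested stratified cross-validated grid search.

    Inner ``inner_k``-fold CV selects (lambda_l1, lambda_tv) per outer fold;
    the metric is computed on the untouched outer test fold.  Imputation and
    class weights are fitted inside each training fold (no leakage).  Ties
    in the inner score are broken toward the larger total penalty (sparser
    model).  Deterministic given ``seed``.
    """
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fit_kwargs = dict(fit_kwargs or {})
    outer = StratifiedKFold(outer_k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    selected = []
    fold_metrics = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        assignments[te] = f
        inner = StratifiedKFold(inner_k, shuffle=True, random_state=seed + 1 + f)
        results = []
        for lam in grid:
            scores = []
            for itr, iva in inner.split(X[tr], y[tr]):
                Xtr, Xva = impute_missing(X[tr][itr], X[tr][iva])
                model = _fit_task(Xtr, y[tr][itr], lam, edges, ordinal, fit_kwargs)
                scores.append(_score(metric, model, Xva, y[tr][iva]))
            results.append((lam, scores))
        lam = _select_lambda(results, selection_rule)
        selected.append(lam)
        Xtr, Xte = impute_missing(X[tr], X[te])
        model = _fit_task(Xtr, y[tr], lam, edges, ordinal, fit_kwargs)
        fold_metrics.append(_score(metric, model, Xte, y[te]))
    return CVReport(assignments, selected, fold_metrics, metric, seed)


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[tuple[float, float]],
    edges: np.ndarray,
    k: int = 4,
    metric: str = "roc_auc",
    seed: int = 0,
    ordinal: bool = False,
    fit_kwargs: dict | None = None,
    selection_rule: str = "1se",
) -> tuple[StructuredLinearModel, tuple[float, float]]:
    """Plain (non-nested) k-fold grid search; returns the model refitted on
    all data at the selected lambdas."""
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fit_kwargs = dict(fit_kwargs or {})
    cv = StratifiedKFold(k, shuffle=True, random_state=seed)
    results = []
    for lam in grid:
        scores = []
        for tr, te in cv.split(X, y):
            Xtr, Xte = impute_missing(X[tr], X[te])
            model = _fit_task(Xtr, y[tr], lam, edges, ordinal, fit_kwargs)
            scores.append(_score(metric, model, Xte, y[te]))
        results.append((lam, scores))
    lam = _select_lambda(results, selection_rule)
    Xall, _ = impute_missing(X)
    return _fit_task(Xall, y, lam, edges, ordinal, fit_kwargs), lam


def weight_map(model: StructuredLinearModel, atlas=None) -> np.ndarray:
    """Weight map in SD units of the learned weights (w / SD(w)).

    An all-zero model returns all zeros with a warning.  ``atlas`` is
    accepted for interface symmetry (the map is already atlas-aligned).
    """
    w = np.asarray(model.w, dtype=float)
    sd = w.std(ddof=0)
    if sd == 0:
        logger.warning("all-zero weight map; returning zeros")
        return np.zeros_like(w)
    return w / sd
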