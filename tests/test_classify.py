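"""Structured-sparsity classifiers: fits, prediction, CV, and helpers."""

import numpy as np
import pytest
from scipy.special import expit

from shapestage.classify import (
    class_balance_weights,
    fit_logit_tvl1,
    fit_ordit,
    impute_missing,
    nested_cv,
    predict,
    weight_map,
)
from shapestage.errors import ImputationError, LabelError, ParameterError

CHAIN = np.array([(i, i + 1) for i in range(9)])


def _binary_data(rng, n=80, p=10, w_scale=1.0):
    X = rng.normal(0, 1, (n, p))
    w = np.zeros(p)
    w[2:5] = w_scale
    y = (rng.random(n) < expit(X @ w)).astype(int)
    if len(np.unique(y)) < 2:  # pragma: no cover
        y[0] = 1 - y[0]
    return X, y


def test_huge_l1_gives_zero_weights_and_base_rate_intercept(rng):
    X, y = _binary_data(rng)
    model = fit_logit_tvl1(X, y, 1e6, 0.0, CHAIN, max_iter=2000, tol=1e-12)
    assert np.allclose(model.w, 0.0)
    base = y.mean()
    assert model.intercept == pytest.approx(np.log(base / (1 - base)), abs=1e-4)


def test_weighted_base_rate_intercept(rng):
    X, y = _binary_data(rng)
    weights = {0: 2.0, 1: 0.5}
    model = fit_logit_tvl1(X, y, 1e6, 0.0, CHAIN, class_weights=weights, max_iter=2000, tol=1e-12)
    m1 = 0.5 * (y == 1).sum()
    m0 = 2.0 * (y == 0).sum()
    assert model.intercept == pytest.approx(np.log(m1 / m0), abs=1e-4)


def test_separable_direction_matches_unregularized_fit(rng):
    n = 60
    X = np.column_stack([rng.normal(0, 1, n), rng.normal(0, 1, n)])
    y = (X[:, 0] > 0).astype(int)
    model = fit_logit_tvl1(X, y, 0.01, 0.01, np.array([(0, 1)]), max_iter=2000)
    from sklearn.linear_model import LogisticRegression

    ref = LogisticRegression(C=np.inf, max_iter=1000).fit(X, y)
    assert np.sign(model.w[0]) == np.sign(ref.coef_[0, 0])
    assert abs(model.w[0]) > abs(model.w[1])


def test_single_class_raises(rng):
    X = rng.normal(0, 1, (10, 3))
    with pytest.raises(LabelError):
        fit_logit_tvl1(X, np.zeros(10), 0.1, 0.1, np.array([(0, 1)]))


def test_objective_trace_nonincreasing(rng):
    X, y = _binary_data(rng)
    model = fit_logit_tvl1(X, y, 0.5, 0.5, CHAIN)
    trace = np.array(model.solver_report["objective_trace"])
    assert (np.diff(trace) <= 1e-10).all()
    mo = fit_ordit(X, y + 1, 0.5, 0.5, CHAIN)
    trace_o = np.array(mo.solver_report["objective_trace"])
    assert (np.diff(trace_o) <= 1e-10).all()


def test_ordit_k2_matches_binary_objective(rng):
    for trial in range(5):
        X, y = _binary_data(rng, n=50, p=8)
        edges = np.array([(i, i + 1) for i in range(7)])
        mb = fit_logit_tvl1(X, y, 0.2, 0.2, edges, max_iter=4000, tol=1e-13)
        mo = fit_ordit(X, y + 1, 0.2, 0.2, edges, max_iter=4000, tol=1e-13)
        assert mo.solver_report["objective"] == pytest.approx(
            mb.solver_report["objective"], abs=1e-6
        )
        assert mo.thresholds[0] == pytest.approx(-mb.intercept, abs=1e-3)


def test_ordit_thresholds_strictly_increasing(rng):
    n, p, K = 150, 10, 4
    X = rng.normal(0, 1, (n, p))
    w = np.zeros(p)
    w[:3] = 1.0
    z = X @ w + rng.normal(0, 0.5, n)
    y = np.digitize(z, np.quantile(z, [0.25, 0.5, 0.75])) + 1
    model = fit_ordit(X, y, 0.3, 0.3, CHAIN, max_iter=1000)
    assert (np.diff(model.thresholds) > 0).all()
    assert model.K == K


def test_ordit_rejects_noncontiguous_labels(rng):
    X = rng.normal(0, 1, (30, 4))
    y = np.array([1, 3] * 15)  # missing class 2
    with pytest.raises(LabelError, match="contiguous"):
        fit_ordit(X, y, 0.1, 0.1, np.array([(0, 1)]))


def test_predict_binary_zero_model_is_half(rng):
    from shapestage.classify import StructuredLinearModel

    model = StructuredLinearModel(np.zeros(4), 0.0, None, 2, 0, 0, {"classes": [0, 1]})
    prob, _ = predict(model, rng.normal(0, 1, (7, 4)))
    np.testing.assert_array_equal(prob, 0.5)


def test_predict_ordinal_probs_sum_to_one(rng):
    n, p = 40, 6
    X = rng.normal(0, 1, (n, p))
    y = rng.integers(1, 4, n)
    y[:3] = [1, 2, 3]
    model = fit_ordit(X, y, 0.2, 0.2, np.array([(i, i + 1) for i in range(p - 1)]), max_iter=300)
    probs, labels = predict(model, X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert set(labels) <= {1, 2, 3}


def test_predict_at_threshold_is_half(rng):
    from shapestage.classify import StructuredLinearModel

    w = np.array([1.0, 0.0])
    thresholds = np.array([0.7, 1.9])
    model = StructuredLinearModel(w, None, thresholds, 3, 0, 0, {"classes": [1, 2, 3]})
    X = np.array([[0.7, 5.0]])  # w'x = theta_1 exactly
    probs, _ = predict(model, X)
    assert probs[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_ordinal_decision_monotone_in_score(rng):
    from shapestage.classify import StructuredLinearModel

    model = StructuredLinearModel(np.array([1.0]), None, np.array([-1.0, 1.0]), 3, 0, 0, {"classes": [1, 2, 3]})
    X = np.linspace(-5, 5, 101)[:, None]
    _, labels = predict(model, X)
    assert (np.diff(labels) >= 0).all()


def test_impute_no_missing_is_identity(rng):
    X = rng.normal(0, 1, (10, 3))
    out, _ = impute_missing(X)
    np.testing.assert_array_equal(out, X)


def test_impute_uses_training_mean_not_test_mean(rng):
    Xtr = rng.normal(0, 1, (50, 2))
    Xte = rng.normal(5, 1, (20, 2))  # shifted test distribution
    Xte[0, 0] = np.nan
    _, filled = impute_missing(Xtr, Xte)
    assert filled[0, 0] == pytest.approx(np.nanmean(Xtr[:, 0]))


def test_impute_fully_missing_column_raises():
    X = np.full((5, 2), np.nan)
    X[:, 1] = 1.0
    with pytest.raises(ImputationError, match="0"):
        impute_missing(X)


def test_class_balance_weights_formula():
    y = np.array([0] * 90 + [1] * 10)
    w = class_balance_weights(y)
    assert w[0] == pytest.approx(100 / (2 * 90))
    assert w[1] == pytest.approx(5.0)
    # weighted class masses equal; weights sum to n over subjects
    assert sum(w[v] for v in y) == pytest.approx(100)
    balanced = class_balance_weights(np.array([0, 1, 0, 1]))
    assert balanced[0] == balanced[1] == 1.0


def test_nested_cv_perfect_feature_gives_auc_one(rng):
    n = 80
    X = np.column_stack([np.linspace(-2, 2, n), rng.normal(0, 1, n)])
    y = (X[:, 0] > 0).astype(int)
    rep = nested_cv(
        X, y, [(0.01, 0.01)], np.array([(0, 1)]), outer_k=4, inner_k=2,
        metric="roc_auc", seed=0, fit_kwargs={"max_iter": 300},
    )
    assert rep.mean_metric == 1.0
    # folds partition the subjects
    assert sorted(np.unique(rep.outer_assignments)) == [0, 1, 2, 3]


def test_nested_cv_deterministic(rng):
    X, y = _binary_data(rng, n=60)
    kw = dict(outer_k=3, inner_k=2, metric="roc_auc", seed=5, fit_kwargs={"max_iter": 100})
    r1 = nested_cv(X, y, [(0.1, 0.1), (1.0, 1.0)], CHAIN, **kw)
    r2 = nested_cv(X, y, [(0.1, 0.1), (1.0, 1.0)], CHAIN, **kw)
    assert r1.fold_metrics == r2.fold_metrics
    assert r1.selected == r2.selected


def test_nested_cv_empty_grid_raises(rng):
    X, y = _binary_data(rng)
    with pytest.raises(ParameterError):
        nested_cv(X, y, [], CHAIN)


def test_weight_map_sd_units(rng):
    from shapestage.classify import StructuredLinearModel

    w = rng.normal(0, 2, 30)
    model = StructuredLinearModel(w, 0.0, None, 2, 0, 0, {})
    wm = weight_map(model)
    assert wm.std(ddof=0) == pytest.approx(1.0)
    np.testing.assert_array_equal(np.sign(wm), np.sign(w))
    zero = StructuredLinearModel(np.zeros(5), 0.0, None, 2, 0, 0, {})
    np.testing.assert_array_equal(weight_map(zero), 0.0)
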