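"""Boosting primitives against closed forms, tree mechanics, determinism
and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from hdx2ss._errors import DegenerateTargetError, ValidationError
from hdx2ss.gb_core import (
    FeatureTable,
    GBConfig,
    GBModel,
    cross_entropy,
    feature_importance,
    fit,
    fit_tree,
    grid_search,
    initial_log_odds,
    leaf_gamma,
    predict_proba,
    prob_from_log_odds,
    pseudo_residuals,
)


# ---------------------------------------------------------------------------
# primitives

def test_initial_log_odds_closed_form():
    y = [1, 0, 0, 0]
    assert initial_log_odds(y) == pytest.approx(math.log(0.25 / 0.75), abs=1e-15)
    assert initial_log_odds([0, 1]) == pytest.approx(0.0, abs=1e-15)


def test_single_class_targets_raise():
    with pytest.raises(DegenerateTargetError):
        initial_log_odds([1, 1, 1])
    with pytest.raises(DegenerateTargetError):
        initial_log_odds([0, 0])


def test_logistic_transform_is_stable_and_correct():
    assert prob_from_log_odds(0.0) == pytest.approx(0.5)
    assert prob_from_log_odds(1000.0) == 1.0
    assert prob_from_log_odds(-1000.0) == 0.0
    z = np.linspace(-30, 30, 101)
    assert np.allclose(prob_from_log_odds(z), 1.0 / (1.0 + np.exp(-z)), atol=1e-15)


def test_pseudo_residuals_equal_negative_loss_gradient():
    # r_i = y_i - p_i must match the central finite difference of the
    # cross-entropy with respect to each sample's log-odds
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=20)
    z = rng.normal(size=20)
    p = prob_from_log_odds(z)
    r = pseudo_residuals(y, p)
    h = 1e-6
    for i in range(20):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        dloss = (cross_entropy(y, prob_from_log_odds(zp)) - cross_entropy(y, prob_from_log_odds(zm))) / (2 * h)
        assert -dloss == pytest.approx(r[i], abs=1e-6)


def test_leaf_gamma_matches_scalar_loss_minimizer():
    # the Newton-step gamma approximates the argmin of the leaf's
    # cross-entropy as a function of a constant log-odds increment
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=40)
    z = rng.normal(scale=0.5, size=40)
    p = prob_from_log_odds(z)
    r = pseudo_residuals(y, p)
    gamma = leaf_gamma(r, p)
    exact = minimize_scalar(
        lambda g: cross_entropy(y, prob_from_log_odds(z + g)), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    ).x
    assert gamma == pytest.approx(exact, abs=1e-3)


def test_leaf_gamma_caps_on_saturated_probabilities(caplog):
    with caplog.at_level("WARNING"):
        assert leaf_gamma([0.5, 0.5], [1.0, 1.0]) == 10.0
        assert leaf_gamma([-0.5], [0.0]) == -10.0
    with pytest.raises(ValidationError):
        leaf_gamma([], [])


def test_cross_entropy_manual_value_and_clipping(caplog):
    assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(-2 * math.log(0.5))
    with caplog.at_level("WARNING"):
        val = cross_entropy([1], [0.0])
    assert np.isfinite(val)
    assert any("clipped" in r.message for r in caplog.records)


@given(st.integers(0, 2**31 - 1))
def test_pseudo_residuals_bounded(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=10)
    p = rng.uniform(0.01, 0.99, size=10)
    r = pseudo_residuals(y, p)
    assert (np.abs(r) <= 1.0).all()


# ---------------------------------------------------------------------------
# trees

def test_tree_finds_obvious_split():
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]] * 2)
    r = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0] * 2)
    p = np.full(12, 0.5)
    tree = fit_tree(X, r, p, GBConfig(n_stages=1, max_leaf_nodes=2, min_samples_leaf=2))
    splits = tree.splits()
    assert len(splits) == 1
    assert splits[0].feature == 0
    assert splits[0].threshold == pytest.approx(6.0)  # midpoint of 2 and 10
    assert tree.predict(np.array([[0.0]]))[0] < 0 < tree.predict(np.array([[12.0]]))[0]


def test_tie_breaks_choose_lowest_feature_then_threshold():
    # two identical features: the split must use feature 0
    col = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0] * 2)
    X = np.column_stack([col, col])
    r = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0] * 2)
    p = np.full(12, 0.5)
    tree = fit_tree(X, r, p, GBConfig(max_leaf_nodes=2, min_samples_leaf=2))
    assert tree.splits()[0].feature == 0


def test_min_samples_leaf_is_respected():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 3))
    r = rng.normal(size=60)
    p = np.full(60, 0.5)
    tree = fit_tree(X, r, p, GBConfig(max_leaf_nodes=8, min_samples_leaf=7))
    stack = [(tree.root)]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            assert node.n_samples >= 7
        else:
            stack.extend([node.left, node.right])


def test_max_leaf_nodes_is_respected():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 4))
    r = rng.normal(size=200)
    p = np.full(200, 0.5)
    for cap in (2, 4, 8):
        tree = fit_tree(X, r, p, GBConfig(max_leaf_nodes=cap, min_samples_leaf=1))
        n_leaves = len(tree.splits()) + 1
        assert n_leaves <= cap


# ---------------------------------------------------------------------------
# boosting

def _toy_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    logit = 2.0 * X[:, 0] - 1.0 * X[:, 1]
    y = (rng.random(n) < prob_from_log_odds(logit)).astype(int)
    return FeatureTable(X=X, y=y)


def test_zero_learning_rate_freezes_the_model():
    table = _toy_table()
    model = fit(table, GBConfig(n_stages=10, nu=0.0))
    p = predict_proba(model, table.X)
    assert np.allclose(p, table.y.mean(), atol=1e-12)
    assert np.allclose(np.diff(model.loss_trajectory), 0.0, atol=1e-9)


def test_training_loss_decreases():
    table = _toy_table()
    model = fit(table, GBConfig(n_stages=50, nu=0.2))
    traj = model.loss_trajectory
    assert traj[-1] < traj[0]
    # cross-entropy against a held-in set must improve early on
    assert traj[10] < traj[0]


def test_fit_is_deterministic():
    table = _toy_table()
    m1 = fit(table, GBConfig(n_stages=25, seed=3))
    m2 = fit(table, GBConfig(n_stages=25, seed=3))
    assert np.allclose(predict_proba(m1, table.X), predict_proba(m2, table.X), atol=0)


def test_model_dict_round_trip():
    table = _toy_table()
    model = fit(table, GBConfig(n_stages=15))
    again = GBModel.from_dict(model.to_dict())
    assert np.allclose(predict_proba(again, table.X), predict_proba(model, table.X), atol=1e-15)


def test_decision_function_rejects_wrong_arity():
    table = _toy_table()
    model = fit(table, GBConfig(n_stages=2))
    with pytest.raises(ValidationError):
        model.decision_function(np.zeros((3, 7)))


def test_feature_importance_finds_the_signal():
    table = _toy_table(n=400)
    model = fit(table, GBConfig(n_stages=60))
    imp = feature_importance(model)
    assert imp.sum() == pytest.approx(1.0)
    assert imp[0] == imp.max()  # x0 carries twice the weight of x1
    assert imp[0] > imp[2] and imp[0] > imp[3]


def test_config_validation():
    with pytest.raises(ValidationError):
        GBConfig(nu=1.5)
    with pytest.raises(ValidationError):
        GBConfig(nu=-0.1)
    with pytest.raises(ValidationError):
        GBConfig(n_stages=0)
    GBConfig(nu=0.0)  # allowed for frozen-model diagnostics


def test_feature_table_validation():
    with pytest.raises(ValidationError):
        FeatureTable(X=np.zeros(5), y=np.zeros(5))
    with pytest.raises(ValidationError):
        FeatureTable(X=np.zeros((5, 2)), y=np.zeros(4))
    with pytest.raises(ValidationError):
        FeatureTable(X=np.full((5, 2), np.nan), y=np.zeros(5))
    with pytest.raises(ValidationError):
        FeatureTable(X=np.zeros((5, 2)), y=np.array([0, 1, 2, 0, 1]))


def test_grid_search_prefers_the_better_configuration():
    table = _toy_table(n=300)
    best = grid_search(table, {"n_stages": [1, 60]}, folds=3, seed=0)
    assert best.n_stages == 60
    with pytest.raises(ValidationError):
        grid_search(table, {}, folds=3)
    with pytest.raises(ValidationError):
        grid_search(table, {"n_stages": []}, folds=3)
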