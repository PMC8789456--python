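"""Fuzzy SVM: dual feasibility, oracle equality, membership semantics."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from hemofuse.fsvm import (
    FSVMHyperparams,
    FSVMModel,
    assign_memberships,
    kernel_matrix,
    train_fsvm,
    train_multiclass,
)
from hemofuse.synthetic import linearly_separable_features


def slsqp_dual_oracle(K, y, cap):
    """Independent generic QP solve of the capped dual (SLSQP route)."""
    n = y.size
    Q = (y[:, None] * y[None, :]) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, c) for c in cap],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    assert res.success
    return res.x


def random_binary_set(seed, n=16, d=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:
        y[0] *= -1
    return X, y


# -------------------------------------------------------------- memberships

def test_centroid_point_gets_full_membership():
    # symmetric cloud: one point sits exactly at its class centroid
    X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [5.0, 5.0], [6.0, 5.0]])
    y = np.array([1, 1, 1, -1, -1])
    s = assign_memberships(X, y)
    assert s[0] == 1.0


def test_farthest_point_near_floor():
    X = np.array([[0.0, 0.0], [0.1, 0.0], [100.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
    y = np.array([1, 1, 1, -1, -1])
    s = assign_memberships(X, y, sigma=0.05)
    assert s[2] == pytest.approx(0.05, abs=1e-4)


def test_uniform_scheme_all_ones():
    X, y = random_binary_set(0)
    assert np.all(assign_memberships(X, y, scheme="uniform") == 1.0)


def test_membership_empty_class_rejected():
    with pytest.raises(ValueError):
        train_fsvm(np.zeros((3, 2)), np.array([1.0, 1.0, 1.0]))


# -------------------------------------------------------------- binary training

def test_symmetric_pair_boundary():
    X = np.array([[-1.0, 0.0], [1.0, 0.0]])
    y = np.array([-1.0, 1.0])
    m = train_fsvm(X, y, memberships=np.ones(2),
                   hp=FSVMHyperparams(C=1e3, kernel="linear"))
    assert m.alpha[0] == pytest.approx(m.alpha[1], abs=1e-9)
    assert np.allclose(m.w, [1.0, 0.0], atol=1e-8)
    assert m.bias == pytest.approx(0.0, abs=1e-8)
    dec = m.decision_function([[0.0, 5.0]])
    assert dec[0] == pytest.approx(0.0, abs=1e-8)
    assert m.predict([[0.0, 5.0]])[0] == 1  # sign(0) -> +1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_uniform_memberships_match_qp_oracle(seed):
    X, y = random_binary_set(seed)
    hp = FSVMHyperparams(C=5.0, kernel="rbf", gamma=0.5, tol=1e-10)
    model = train_fsvm(X, y, memberships=np.ones(y.size), hp=hp)
    K = kernel_matrix(hp, X, gamma=0.5)
    a_oracle = slsqp_dual_oracle(K, y, np.full(y.size, 5.0))
    assert np.abs(model.alpha - a_oracle).max() < 1e-6


def test_decision_agrees_with_reference_on_random_points():
    X, y = random_binary_set(3, n=20)
    hp = FSVMHyperparams(C=2.0, kernel="rbf", gamma=0.7, tol=1e-10)
    model = train_fsvm(X, y, memberships=np.ones(20), hp=hp)
    sk = SVC(C=2.0, kernel="rbf", gamma=0.7, tol=1e-10).fit(X, y)
    pts = np.random.default_rng(9).normal(size=(100, 3))
    assert np.abs(model.decision_function(pts) - sk.decision_function(pts)).max() < 1e-5


def test_outlier_membership_caps_alpha():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2)),
                   [[2.0, 2.0]]])  # last point: positive-side outlier, labelled -1
    y = np.array([-1.0] * 20 + [1.0] * 20 + [-1.0])
    s = np.ones(41)
    s[-1] = 0.05
    hp = FSVMHyperparams(C=10.0, kernel="linear", tol=1e-10)
    fuzzy = train_fsvm(X, y, memberships=s, hp=hp)
    plain = train_fsvm(X, y, memberships=np.ones(41), hp=hp)
    assert fuzzy.alpha[-1] <= 0.05 * 10.0 + 1e-9
    assert plain.alpha[-1] > fuzzy.alpha[-1]


@pytest.mark.parametrize("seed", [4, 5, 6, 7])
def test_dual_feasibility(seed):
    X, y = random_binary_set(seed, n=24)
    model = train_fsvm(X, y, hp=FSVMHyperparams(C=3.0, tol=1e-10))
    cap = model.memberships * 3.0
    tol = 1e-8
    assert abs(float(model.alpha @ y)) < 1e-7
    assert np.all(model.alpha >= -tol)
    assert np.all(model.alpha <= cap + 1e-7)
    assert np.array_equal(model.support_idx, np.flatnonzero(model.alpha > 1e-10))


def test_lower_membership_never_raises_cap():
    X, y = random_binary_set(8, n=20)
    s = np.ones(20)
    hp = FSVMHyperparams(C=4.0, kernel="rbf", gamma=0.3)
    base = train_fsvm(X, y, memberships=s, hp=hp)
    s2 = s.copy()
    s2[5] = 0.1
    low = train_fsvm(X, y, memberships=s2, hp=hp)
    assert low.alpha[5] <= 0.1 * 4.0 + 1e-9
    assert base.alpha[5] <= 1.0 * 4.0 + 1e-9


def test_duplication_leaves_linear_boundary_unchanged():
    # separable data with all support vectors free (no alpha at its cap):
    # duplicating every point then leaves the dual optimum, hence the
    # boundary, unchanged
    rng = np.random.default_rng(10)
    X = np.vstack([rng.normal(-3, 0.5, (12, 2)), rng.normal(3, 0.5, (12, 2))])
    y = np.array([-1.0] * 12 + [1.0] * 12)
    hp = FSVMHyperparams(C=10.0, kernel="linear", tol=1e-12)
    s = assign_memberships(X, y)
    m1 = train_fsvm(X, y, memberships=s, hp=hp)
    assert np.all(m1.alpha < s * 10.0 - 1e-6)  # caps inactive
    m2 = train_fsvm(np.vstack([X, X]), np.concatenate([y, y]),
                    memberships=np.concatenate([s, s]), hp=hp)
    grid = rng.normal(0, 3, size=(50, 2))
    d1, d2 = m1.decision_function(grid), m2.decision_function(grid)
    assert np.abs(d1 - d2).max() < 1e-5


def test_midpoint_bias_fallback_warns():
    X = np.array([[-1.0, 0.0], [1.0, 0.0]])
    y = np.array([-1.0, 1.0])
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        m = train_fsvm(X, y, memberships=np.ones(2),
                       hp=FSVMHyperparams(C=0.01, kernel="linear"))
    assert m.degenerate
    assert any("free support vectors" in str(w.message) for w in rec)


def test_model_json_roundtrip():
    X, y = random_binary_set(11)
    m = train_fsvm(X, y, hp=FSVMHyperparams(C=2.0))
    m2 = FSVMModel.from_json(m.to_json())
    pts = np.random.default_rng(1).normal(size=(10, 3))
    assert np.allclose(m.decision_function(pts), m2.decision_function(pts))


# -------------------------------------------------------------- multiclass

def test_three_blobs_perfect_training_accuracy():
    X, y = linearly_separable_features(30, 5, 10.0, seed=0, n_classes=3)
    ens = train_multiclass(X, y, hp=FSVMHyperparams(C=10.0))
    assert np.mean(ens.predict(X) == y) == 1.0


def test_two_class_reduction_matches_binary():
    X, y = random_binary_set(12, n=30)
    hp = FSVMHyperparams(C=5.0, kernel="rbf", gamma=0.4)
    ens = train_multiclass(X, y, hp=hp, classes=[-1.0, 1.0])
    binary = train_fsvm(X, y, hp=hp)
    pts = np.random.default_rng(2).normal(size=(40, 3))
    assert np.array_equal(
        np.asarray(ens.predict(pts), dtype=float), binary.predict(pts).astype(float)
    )


def test_class_order_permutation_invariant_off_ties():
    X, y = linearly_separable_features(20, 4, 8.0, seed=1, n_classes=3)
    hp = FSVMHyperparams(C=5.0)
    a = train_multiclass(X, y, hp=hp, classes=[0.0, 1.0, 2.0])
    b = train_multiclass(X, y, hp=hp, classes=[2.0, 0.0, 1.0])
    pts = np.random.default_rng(3).normal(size=(30, 4))
    da, db = a.decision_matrix(pts), b.decision_matrix(pts)
    clear = np.abs(np.sort(da, axis=1)[:, -1] - np.sort(da, axis=1)[:, -2]) > 1e-9
    assert np.array_equal(
        np.asarray(a.predict(pts))[clear], np.asarray(b.predict(pts))[clear]
    )


def test_single_class_rejected():
    with pytest.raises(ValueError):
        train_multiclass(np.zeros((4, 2)), np.zeros(4))
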