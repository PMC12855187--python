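"""OPLS-DA: PLS1 equivalence, orthogonality, CV, permutation, VIP."""

import numpy as np
import pytest

import psametab as pm
from psametab.oplsda import class_folds

from conftest import strong_signal


def nipals_pls1(X, y, tol=1e-12, max_iter=1000):
    """Independent single-component PLS1 oracle (textbook NIPALS)."""
    w = X.T @ y
    w = w / np.linalg.norm(w)
    for _ in range(max_iter):
        t = X @ w
        c = y @ t / (t @ t)
        w_new = X.T @ y
        w_new = w_new / np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < tol:
            break
        w = w_new
    t = X @ w
    c = y @ t / (t @ t)
    return w, t, c


def test_zero_orthogonal_matches_pls1_oracle():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((6, 4))
    X -= X.mean(axis=0)
    y = np.array(["A", "A", "A", "B", "B", "B"])
    model = pm.fit_oplsda(X, y, n_orthogonal=0)
    yd = np.array([0, 0, 0, 1, 1, 1]) - 0.5
    w, t, c = nipals_pls1(X, yd)
    sign = np.sign(w @ model.w)
    np.testing.assert_allclose(model.w, sign * w, atol=1e-8)
    np.testing.assert_allclose(model.predict(X),
                               t * c * sign * sign + 0.5, atol=1e-8)


def test_score_and_weight_orthogonality(rel_conc, default_cohort):
    Xs, _ = pm.pareto_scale(rel_conc.to_numpy())
    model = pm.fit_oplsda(Xs, default_cohort.cohort.group, n_orthogonal=2)
    for a in range(model.n_orthogonal):
        assert abs(model.t @ model.T_o[:, a]) < 1e-8 * np.linalg.norm(model.t) \
            * np.linalg.norm(model.T_o[:, a])
        assert abs(model.w @ model.W_o[:, a]) < 1e-8
    assert np.linalg.norm(model.w) == pytest.approx(1.0)
    assert 0.0 <= model.R2X_cum <= 1.0
    assert 0.0 <= model.R2Y_cum <= 1.0


def test_label_swap_symmetry(rel_conc, default_cohort):
    Xs, _ = pm.pareto_scale(rel_conc.to_numpy())
    y = default_cohort.cohort.group.to_numpy(str)
    swap = {"PsA": "aPsA", "HC": "zHC"}  # reverses the sort order
    y2 = np.array([swap[v] for v in y])
    m1 = pm.fit_oplsda(Xs, y)
    m2 = pm.fit_oplsda(Xs, y2)
    np.testing.assert_allclose(m2.t, -m1.t, atol=1e-10)
    np.testing.assert_allclose(m2.w, -m1.w, atol=1e-10)
    # with both w and t negated the y-loading is invariant, and the
    # predicted class-1 probability flips to its complement
    assert m2.c == pytest.approx(m1.c)
    np.testing.assert_allclose(m2.predict(Xs), 1.0 - m1.predict(Xs),
                               atol=1e-10)
    assert m2.R2Y_cum == pytest.approx(m1.R2Y_cum)
    np.testing.assert_allclose(pm.vip(m2).vip, pm.vip(m1).vip, atol=1e-12)


def test_r2y_near_zero_for_independent_labels():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((400, 5))
    X -= X.mean(axis=0)
    y = np.array(["A", "B"] * 200)
    model = pm.fit_oplsda(X, y, n_orthogonal=0)
    assert model.R2Y_cum < 0.1


def test_q2_above_half_for_separable_data():
    X, y = strong_signal(delta=3.0, seed=5)
    q2 = pm.cross_validate(X, y, folds=7)
    assert q2 > 0.5


def test_q2_nonpositive_for_noise_labels():
    """Median held-out Q2 over repeated pure-noise simulations is < 0."""
    rng = np.random.default_rng(10)
    q2s = []
    for _ in range(50):
        X = rng.standard_normal((24, 8))
        y = rng.permutation(np.array(["A"] * 12 + ["B"] * 12))
        q2s.append(pm.cross_validate(X, y, folds=6))
    assert np.median(q2s) < 0.0


def test_fold_assignment_round_robin():
    y = np.array(["A", "A", "A", "B", "B", "A", "B"])
    assign = class_folds(y, 2)
    np.testing.assert_array_equal(assign, [0, 1, 0, 0, 1, 1, 0])


def test_cv_errors_when_fold_strips_a_class():
    X = np.arange(20, dtype=float).reshape(10, 2)
    y = np.array(["A"] * 7 + ["B"] * 3)
    with pytest.raises(ValueError, match="fewer folds"):
        pm.cross_validate(X, y, folds=4)


def test_single_class_rejected():
    X = np.random.default_rng(0).standard_normal((6, 3))
    with pytest.raises(ValueError):
        pm.fit_oplsda(X, np.array(["A"] * 6))


def test_permutation_summary_contains_original_point():
    X, y = strong_signal(seed=6)
    summ = pm.permutation_test(X, y, n_perm=20, seed=1)
    assert summ.correlations[0] == pytest.approx(1.0)
    assert summ.r2y[0] == pytest.approx(summ.original_R2Y)
    assert summ.q2[0] == pytest.approx(summ.original_Q2)
    assert np.isfinite(summ.Q2_intercept) and np.isfinite(summ.R2_intercept)


def test_permutation_q2_intercept_small_for_strong_signal():
    X, y = strong_signal(delta=3.0, seed=7)
    summ = pm.permutation_test(X, y, n_perm=50, seed=2)
    assert summ.Q2_intercept < 0.05


def test_noise_model_not_better_than_permuted():
    """On signal-free data the original Q2 sits inside the permuted Q2
    distribution (median empirical p over seeds > 0.05)."""
    rng = np.random.default_rng(11)
    ps = []
    for s in range(5):
        X = rng.standard_normal((24, 6))
        y = np.array(["A"] * 12 + ["B"] * 12)
        summ = pm.permutation_test(X, y, n_perm=30, seed=s)
        ps.append(summ.empirical_p())
    assert np.median(ps) > 0.05


def test_vip_identities(rel_conc, default_cohort):
    Xs, _ = pm.pareto_scale(rel_conc.to_numpy())
    model = pm.fit_oplsda(Xs, default_cohort.cohort.group,
                          columns=list(rel_conc.columns))
    v = pm.vip(model)
    assert (v.vip >= 0).all()
    assert (v.vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)
    assert list(v.index) == list(rel_conc.columns)


def test_vip_flags_the_informative_variable():
    """One informative variable among nine noise variables gets the
    maximum VIP, above 1, in a majority of replicates."""
    rng = np.random.default_rng(12)
    wins = 0
    for _ in range(50):
        X = rng.standard_normal((30, 10))
        y = np.array(["A"] * 15 + ["B"] * 15)
        X[:15, 0] += 2.5
        Xs, _ = pm.pareto_scale(X)
        v = pm.vip(pm.fit_oplsda(Xs, y))
        wins += (v.vip.idxmax() == "var0") and (v.vip.loc["var0"] > 1)
    assert wins > 25


def test_vip_equal_weights_give_unit_vip():
    model = pm.fit_oplsda(np.array([[1.0, 1.0]] * 3 + [[-1.0, -1.0]] * 3),
                          np.array(["A"] * 3 + ["B"] * 3), n_orthogonal=0)
    np.testing.assert_allclose(pm.vip(model).vip, 1.0, atol=1e-12)
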