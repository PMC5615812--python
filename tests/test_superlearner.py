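"""Stacking ensemble: out-of-fold structure against a hand loop, simplex
weight feasibility and grid-search agreement, and leave-one-exposure-out
importance."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression, Ridge

from ersmix.superlearner import (
    Learner,
    LearnerRegistry,
    compute_ers_sl,
    fit_superlearner,
    generate_cv_level1,
    sl_variable_importance,
    solve_ensemble_weights,
)


def _sk_learner(name, factory):
    def fit(X, y, seed):
        est = factory()
        est.fit(X, y)
        return est

    return Learner(name, fit, lambda est, X: est.predict(X))


def _mean_learner(name="mean"):
    return Learner(
        name,
        fit=lambda X, y, seed: float(np.mean(y)),
        predict=lambda mu, X: np.full(len(X), mu),
    )


def _small_registry():
    return LearnerRegistry(
        [
            _mean_learner(),
            _sk_learner("ols", LinearRegression),
            _sk_learner("ridge", lambda: Ridge(alpha=1.0)),
        ]
    )


class TestLevel1:
    def test_mean_column_is_per_fold_training_mean(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        reg = LearnerRegistry([_mean_learner()])
        level1, fold_of, names = generate_cv_level1(reg, X, y, V=3, seed=5)
        assert names == ["mean"]
        for v in range(3):
            va = fold_of == v
            assert np.allclose(level1[va, 0], y[~va].mean())

    def test_loo_structure_excludes_own_subject(self, rng):
        y = np.arange(10.0)
        X = rng.standard_normal((10, 2))
        reg = LearnerRegistry([_mean_learner()])
        level1, fold_of, _ = generate_cv_level1(reg, X, y, V=10, seed=1)
        assert sorted(np.bincount(fold_of)) == [1] * 10
        for i in range(10):
            assert level1[i, 0] == pytest.approx(np.delete(y, i).mean())

    def test_same_seed_same_folds(self, rng):
        X, y = rng.standard_normal((40, 2)), rng.standard_normal(40)
        reg = _small_registry()
        _, f1, _ = generate_cv_level1(reg, X, y, V=4, seed=9)
        _, f2, _ = generate_cv_level1(reg, X, y, V=4, seed=9)
        assert np.array_equal(f1, f2)

    def test_failing_learner_dropped(self, rng):
        def broken_fit(X, y, seed):
            raise ValueError("boom")

        reg = LearnerRegistry(
            [_mean_learner(), Learner("broken", broken_fit, lambda s, X: X[:, 0])]
        )
        X, y = rng.standard_normal((20, 2)), rng.standard_normal(20)
        with pytest.warns(UserWarning, match="broken"):
            level1, _, names = generate_cv_level1(reg, X, y, V=2, seed=0)
        assert names == ["mean"] and level1.shape[1] == 1

    def test_all_fail_is_error(self, rng):
        def broken_fit(X, y, seed):
            raise ValueError("boom")

        reg = LearnerRegistry([Learner("broken", broken_fit, lambda s, X: X[:, 0])])
        with pytest.warns(UserWarning):
            with pytest.raises(RuntimeError, match="all learners failed"):
                generate_cv_level1(reg, rng.standard_normal((10, 1)),
                                   rng.standard_normal(10), V=2, seed=0)


class TestWeights:
    def test_single_learner_weight_one(self, rng):
        a = solve_ensemble_weights(rng.standard_normal((20, 1)), rng.standard_normal(20))
        assert np.array_equal(a, [1.0])

    def test_exact_column_match_concentrates(self, rng):
        level1 = rng.standard_normal((100, 3))
        targets = level1[:, 0]
        a = solve_ensemble_weights(level1, targets)
        assert a[0] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(a[1:]).max() < 1e-6

    def test_feasibility_and_vertex_dominance(self, rng):
        level1 = rng.standard_normal((200, 4))
        targets = level1 @ [0.3, 0.3, 0.2, 0.2] + rng.normal(0, 0.1, 200)
        a = solve_ensemble_weights(level1, targets)
        assert a.min() >= 0.0
        assert abs(a.sum() - 1.0) < 1e-10
        loss = np.sum((targets - level1 @ a) ** 2)
        for m in range(4):
            vertex_loss = np.sum((targets - level1[:, m]) ** 2)
            assert loss <= vertex_loss + 1e-9

    def test_matches_simplex_grid_search(self, rng):
        level1 = rng.standard_normal((150, 3))
        targets = level1 @ [0.5, 0.2, 0.3] + rng.normal(0, 0.3, 150)
        a = solve_ensemble_weights(level1, targets)
        best_loss = np.inf
        for w1 in np.arange(0, 1.0001, 0.01):
            for w2 in np.arange(0, 1.0001 - w1, 0.01):
                w = np.array([w1, w2, 1.0 - w1 - w2])
                loss = np.sum((targets - level1 @ w) ** 2)
                best_loss = min(best_loss, loss)
        achieved = np.sum((targets - level1 @ a) ** 2)
        assert achieved <= best_loss + 0.02 * abs(best_loss)

    def test_zero_columns_rejected(self, rng):
        with pytest.raises(ValueError):
            solve_ensemble_weights(np.empty((10, 0)), rng.standard_normal(10))


class TestErsSl:
    def test_concentrated_weights_reduce_to_single_learner(self, rng):
        X, y = rng.standard_normal((60, 3)), rng.standard_normal(60)
        fit = fit_superlearner(_small_registry(), X, y, V=3, seed=2)
        fit.weights = np.array([0.0, 1.0, 0.0])  # all mass on ols
        out = compute_ers_sl(fit, X)
        direct = fit.registry["ols"].predict(fit.refits["ols"], X)
        assert np.allclose(out.values, direct)

    def test_half_half_weights_average(self, rng):
        X, y = rng.standard_normal((60, 3)), rng.standard_normal(60)
        fit = fit_superlearner(_small_registry(), X, y, V=3, seed=2)
        fit.weights = np.array([0.5, 0.5, 0.0])
        out = compute_ers_sl(fit, X)
        p1 = fit.registry["mean"].predict(fit.refits["mean"], X)
        p2 = fit.registry["ols"].predict(fit.refits["ols"], X)
        assert np.allclose(out.values, 0.5 * p1 + 0.5 * p2)

    def test_duplicated_learner_invariance(self, rng):
        X = rng.standard_normal((80, 3))
        y = X @ [1.0, 0.5, 0.0] + rng.normal(0, 0.3, 80)
        base = LearnerRegistry([_mean_learner(), _sk_learner("ols", LinearRegression)])
        dup = LearnerRegistry(
            [
                _mean_learner(),
                _sk_learner("ols", LinearRegression),
                _sk_learner("ols2", LinearRegression),
            ]
        )
        f1 = fit_superlearner(base, X, y, V=4, seed=3)
        f2 = fit_superlearner(dup, X, y, V=4, seed=3)
        assert np.allclose(compute_ers_sl(f1, X).values,
                           compute_ers_sl(f2, X).values, atol=1e-6)


class TestImportance:
    def test_formula(self):
        assert (125.0 - 100.0) / 100.0 == 0.25

    def test_null_exposure_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 3))
            y = X @ [1.0, 0.8, 0.0] + rng.normal(0, 0.5, 150)
            imp = sl_variable_importance(
                _small_registry(), X, y, ["a", "b", "null"], V=5, seed=seed
            )
            vals.append(imp.table.set_index("exposure").loc["null", "importance"])
        assert abs(np.mean(vals)) < 0.05

    def test_active_exposure_is_maximum(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((150, 4))
            y = 2.0 * X[:, 2] + rng.normal(0, 0.5, 150)
            imp = sl_variable_importance(
                _small_registry(), X, y, list("abcd"), V=5, seed=seed
            )
            t = imp.table.set_index("exposure")["importance"]
            wins += int(t.idxmax() == "c")
        assert wins >= 9
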