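"""Penalized-regression engine against closed-form oracles: ridge normal
equations, per-coordinate soft thresholding on orthonormal designs, and
selection behaviour on simulated sparse truths."""

import numpy as np
import pytest

from ersmix.aenet import (
    compute_ers_linear,
    fit_adaptive_elastic_net,
    fit_elastic_net,
)
from ersmix.preprocessing import expand_interactions


def _orthonormal_centered(rng, n, p):
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, :p]


class TestElasticNet:
    def test_zero_outcome_gives_zero(self, rng):
        X = rng.standard_normal((50, 5))
        beta, b0 = fit_elastic_net(X, np.zeros(50), 1.0, 1.0)
        assert np.allclose(beta, 0.0) and b0 == 0.0

    def test_ridge_matches_normal_equations(self, rng):
        n, p = 120, 8
        X = rng.standard_normal((n, p))
        y = X @ rng.normal(0, 1, p) + rng.normal(0, 0.5, n)
        lam2 = 7.3
        beta, _ = fit_elastic_net(X, y, 0.0, lam2)
        Xc, yc = X - X.mean(0), y - y.mean()
        oracle = np.linalg.solve(Xc.T @ Xc + lam2 * np.eye(p), Xc.T @ yc)
        assert np.max(np.abs(beta - oracle)) < 1e-6

    def test_orthonormal_soft_threshold(self, rng):
        n, p = 200, 6
        Q = _orthonormal_centered(rng, n, p)
        y = rng.standard_normal(n)
        lam1 = 0.8
        beta, _ = fit_elastic_net(Q, y, lam1, 0.0)
        z = Q.T @ (y - y.mean())
        oracle = np.sign(z) * np.maximum(np.abs(z) - lam1 / 2.0, 0.0)
        assert np.max(np.abs(beta - oracle)) < 1e-6

    def test_penalty_factor_zero_unpenalized(self, rng):
        n = 150
        X = rng.standard_normal((n, 3))
        y = X @ [2.0, 0.0, 0.0] + rng.normal(0, 0.3, n)
        pf = np.array([0.0, 1.0, 1.0])
        beta, _ = fit_elastic_net(X, y, 50.0, 0.0, penalty_factors=pf)
        # heavy L1 kills the penalized terms but not the free one
        assert beta[1] == 0.0 and beta[2] == 0.0
        assert beta[0] == pytest.approx(2.0, abs=0.1)

    def test_column_order_invariance(self, rng):
        X = rng.standard_normal((100, 6))
        y = rng.standard_normal(100)
        perm = rng.permutation(6)
        b1, _ = fit_elastic_net(X, y, 2.0, 1.0)
        b2, _ = fit_elastic_net(X[:, perm], y, 2.0, 1.0)
        assert np.max(np.abs(b1[perm] - b2)) < 1e-8

    def test_monotone_screening_on_orthonormal_path(self, rng):
        # on an orthonormal design the lasso path is exact soft
        # thresholding, so support size is non-decreasing as lam1 falls
        Q = _orthonormal_centered(rng, 300, 10)
        y = Q @ rng.normal(0, 2, 10) + rng.normal(0, 0.5, 300)
        sizes = []
        lam_seq = np.geomspace(10.0, 0.001, 30)
        beta = np.zeros(10)
        for lam1 in lam_seq:
            beta, _ = fit_elastic_net(Q, y, lam1, 0.5, beta0=beta)
            sizes.append(int((beta != 0).sum()))
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_elastic_net(rng.standard_normal((10, 2)), np.ones(10), -1.0, 0.0)


class TestAdaptiveElasticNet:
    def _fit(self, X, y, n_cov=0, **kw):
        p = X.shape[1]
        terms = [f"c{j}" for j in range(n_cov)] + [f"m{j}" for j in range(p - n_cov)]
        types = {t: ("covariate" if t.startswith("c") else "main") for t in terms}
        free = np.array([True] * n_cov + [False] * (p - n_cov))
        return fit_adaptive_elastic_net(X, y, terms, types, free, **kw)

    def test_pure_noise_selects_nothing_1se(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 8))
            y = rng.standard_normal(200)
            try:
                fit = self._fit(X, y, seed=seed, rule="1se")
                sizes.append(len(fit.selected))
            except RuntimeError:
                # stage 1 found literally nothing anywhere: size 0
                sizes.append(0)
        assert np.median(sizes) == 0

    def test_recovers_true_mains(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, p = 2000, 10
            X = rng.standard_normal((n, p))
            beta_true = np.zeros(p)
            beta_true[[0, 4, 7]] = [0.25, -0.3, 0.2]
            y = X @ beta_true + rng.normal(0, 1.0, n)
            fit = self._fit(X, y, seed=seed)
            if {"m0", "m4", "m7"} <= set(fit.selected):
                hits += 1
        assert hits >= 18

    def test_unpenalized_covariate_limit(self, rng):
        n = 400
        Z = rng.standard_normal((n, 1))
        X = np.column_stack([Z, rng.standard_normal((n, 3))])
        y = 1.5 * Z[:, 0] + X[:, 1] * 0.8 + rng.normal(0, 0.4, n)
        fit = self._fit(
            X, y, n_cov=1, seed=0,
            lambda2_grid=np.array([0.0]), n_lambda1=30, lambda1_decades=6.0,
        )
        # at vanishing penalty the covariate coefficient matches the
        # unpenalized OLS refit with the selected exposures held fixed
        sel_idx = [0] + [1 + int(t[1:]) for t in fit.selected]
        D = np.column_stack([np.ones(n), X[:, sel_idx]])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert fit.coef[0] == pytest.approx(ols[1], abs=0.02)
        assert fit.se["c0"] > 0 and 0 <= fit.pvalues["m1"] <= 1


class TestErsLinear:
    def _design(self, rng, n=40, p=4):
        E = rng.standard_normal((n, p))
        return expand_interactions(E, [f"m{j}" for j in range(p)])

    def _fit_from(self, design, coef_map):
        from ersmix.aenet import PenalizedFit

        terms = list(design.names)
        coef = np.array([coef_map.get(t, 0.0) for t in terms])
        return PenalizedFit(
            terms=terms, coef=coef, intercept=0.5, lam1=1.0, lam2=0.0,
            omega=np.ones(len(terms)), penalty_factors=np.ones(len(terms)),
            term_types={t: design.index_map[t]["type"] for t in terms},
            selected=[t for t, c in coef_map.items() if c != 0.0],
        )

    def test_all_zero_gives_zero(self, rng):
        d = self._design(rng)
        assert np.allclose(compute_ers_linear(self._fit_from(d, {}), d).values, 0.0)

    def test_single_term_equals_column(self, rng):
        d = self._design(rng)
        ers = compute_ers_linear(self._fit_from(d, {"m2": 1.0}), d)
        assert np.array_equal(ers.values, d.columns(["m2"])[:, 0])

    def test_matches_explicit_loop(self, rng):
        d = self._design(rng, n=25, p=5)
        coef_map = {"m0": 0.4, "m3": -1.2, "m1xm4": 0.7, "m2xm3": -0.1}
        ers = compute_ers_linear(self._fit_from(d, coef_map), d)
        oracle = np.zeros(25)
        for t, c in coef_map.items():
            oracle += c * d.columns([t])[:, 0]
        assert np.max(np.abs(ers.values - oracle)) < 1e-10

    def test_missing_column_named(self, rng):
        d = self._design(rng)
        fit = self._fit_from(d, {"m1": 1.0})
        fit.terms.append("ghost")
        fit.coef = np.append(fit.coef, 2.0)
        fit.term_types["ghost"] = "main"
        with pytest.raises(KeyError, match="ghost"):
            compute_ers_linear(fit, d)
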