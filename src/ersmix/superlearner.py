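"""V-fold cross-validated stacking (super learning) on residualized data.

Base learners are registered by name; each exposes ``fit`` and
``predict``.  Level-1 predictions are strictly out-of-fold, the ensemble
weight vector lives on the probability simplex and minimizes the V-fold
cross-validated squared loss (solved by non-negative least squares then
normalization, with an exact simplex QP available), and the final ERS is
the weighted sum of the full-data refits' predictions.  Variable
importance for exposure j is (SSE(-j) - SSE)/SSE where SSE is the
cross-validated sum of squared ensemble errors and SSE(-j) the same after
omitting exposure j, with fold splits held fixed across reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression, Ridge

from .core import ERSVector

__all__ = [
    "Learner",
    "LearnerRegistry",
    "default_registry",
    "EnsembleFit",
    "generate_cv_level1",
    "solve_ensemble_weights",
    "fit_superlearner",
    "compute_ers_sl",
    "sl_variable_importance",
]


@dataclass
class Learner:
    name: str
    fit: Callable[[np.ndarray, np.ndarray, int], object]
    predict: Callable[[object, np.ndarray], np.ndarray]


class LearnerRegistry:
    """Named, seed-deterministic base learners."""

    def __init__(self, learners: list[Learner] | None = None):
        self._learners: dict[str, Learner] = {}
        for lrn in learners or []:
            self.add(lrn)

    def add(self, learner: Learner) -> None:
        if learner.name in self._learners:
            raise ValueError(f"duplicate learner name: {learner.name!r}")
        self._learners[learner.name] = learner

    @property
    def names(self) -> list[str]:
        return list(self._learners)

    def __getitem__(self, name: str) -> Learner:
        return self._learners[name]

    def __len__(self) -> int:
        return len(self._learners)


def _sk(est_factory):
    def fit(X, y, seed):
        est = est_factory(seed)
        est.fit(X, y)
        return est

    def predict(est, X):
        return est.predict(X)

    return fit, predict


def _mean_learner() -> Learner:
    return Learner(
        "mean",
        fit=lambda X, y, seed: float(np.mean(y)),
        predict=lambda mu, X: np.full(len(X), mu),
    )


def _enet_learner() -> Learner:
    # small internal tuning via our own coordinate descent
    from .aenet import fit_elastic_net

    def fit(X, y, seed):
        n = len(y)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        parts = np.array_split(perm, 3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        lam_max = 2.0 * np.abs(Xc.T @ yc).max() + 1e-12
        lam_seq = np.geomspace(lam_max, lam_max * 1e-3, 15)
        errs = np.zeros(len(lam_seq))
        for part in parts:
            tr = np.setdiff1d(perm, part)
            beta = np.zeros(X.shape[1])
            for i, lam1 in enumerate(lam_seq):
                beta, b0 = fit_elastic_net(
                    X[tr], y[tr], lam1, 0.0, beta0=beta, tol=1e-7
                )
                errs[i] += np.mean((y[part] - (X[part] @ beta + b0)) ** 2)
        lam_best = lam_seq[int(np.argmin(errs))]
        return fit_elastic_net(X, y, lam_best, 0.0, tol=1e-7)

    def predict(state, X):
        beta, b0 = state
        return X @ beta + b0

    return Learner("enet", fit=fit, predict=predict)


def _bart_learner(m: int = 10, iterations: int = 150, burn_in: int = 50) -> Learner:
    from .bart import compute_ers_bart, fit_bart

    def fit(X, y, seed):
        return fit_bart(X, y, m=m, iterations=iterations, burn_in=burn_in, seed=seed)

    def predict(model, X):
        return compute_ers_bart(model, X).values

    return Learner("trees", fit=fit, predict=predict)


def default_registry(fast: bool = False) -> LearnerRegistry:
    """Seven-learner roster spanning the method families used in stacking:
    constant, linear, ridge, elastic net, kernel ridge, sum-of-trees,
    boosted stumps.  ``fast=True`` trims iteration counts for desk-scale
    runs."""
    ols_fit, ols_pred = _sk(lambda seed: LinearRegression())
    ridge_fit, ridge_pred = _sk(lambda seed: Ridge(alpha=1.0))
    kr_fit, kr_pred = _sk(
        lambda seed: KernelRidge(alpha=1.0, kernel="rbf", gamma=None)
    )
    gb_fit, gb_pred = _sk(
        lambda seed: GradientBoostingRegressor(
            max_depth=1,
            n_estimators=50 if fast else 100,
            random_state=seed % (2**31),
        )
    )
    return LearnerRegistry(
        [
            _mean_learner(),
            Learner("ols", ols_fit, ols_pred),
            Learner("ridge", ridge_fit, ridge_pred),
            _enet_learner(),
            Learner("kernel_ridge", kr_fit, kr_pred),
            _bart_learner(iterations=100 if fast else 150),
            Learner("gb_stumps", gb_fit, gb_pred),
        ]
    )


@dataclass
class EnsembleFit:
    """Fold structure, level-1 matrix, simplex weights, full-data refits."""

    V: int
    fold_of: np.ndarray  # fold index per subject
    learner_names: list[str]
    level1: np.ndarray  # (n, M) out-of-fold predictions
    weights: np.ndarray  # (M,), >= 0, sums to 1
    refits: dict[str, object]
    registry: LearnerRegistry
    fit_id: str = ""

    def weight_table(self) -> pd.DataFrame:
        return pd.DataFrame({"learner": self.learner_names, "weight": self.weights})


def _make_folds(n: int, V: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for v, part in enumerate(np.array_split(perm, V)):
        fold_of[part] = v
    return fold_of


def generate_cv_level1(
    registry: LearnerRegistry,
    X: np.ndarray,
    y: np.ndarray,
    V: int = 10,
    seed: int = 0,
    fold_of: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Out-of-fold predictions for every subject and learner.

    A learner that fails on any fold is dropped with a warning; if all
    fail, an error is raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if V < 2:
        raise ValueError("V must be >= 2")
    if fold_of is None:
        fold_of = _make_folds(n, V, seed)
    names = registry.names
    level1 = np.full((n, len(names)), np.nan)
    ok = np.ones(len(names), dtype=bool)
    for v in range(V):
        va = np.where(fold_of == v)[0]
        tr = np.where(fold_of != v)[0]
        for mi, name in enumerate(names):
            if not ok[mi]:
                continue
            lrn = registry[name]
            try:
                state = lrn.fit(X[tr], y[tr], seed + 1000 * v + mi)
                level1[va, mi] = lrn.predict(state, X[va])
            except Exception as exc:  # noqa: BLE001 - learner isolation
                warnings.warn(f"learner {name!r} failed on fold {v}: {exc}; dropped")
                ok[mi] = False
    if not ok.any():
        raise RuntimeError("all learners failed")
    kept = [nm for nm, o in zip(names, ok) if o]
    return level1[:, ok], fold_of, kept


def solve_ensemble_weights(
    level1: np.ndarray, targets: np.ndarray, exact: bool = False
) -> np.ndarray:
    """Simplex weights minimizing ||targets - level1 a||^2.

    Default: non-negative least squares followed by normalization (the
    standard practical solver for this estimator).  ``exact=True`` solves
    the constrained program directly (SLSQP), seeded from the NNLS point.
    """
    level1 = np.asarray(level1, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if level1.ndim != 2 or level1.shape[1] == 0:
        raise ValueError("level1 must have at least one column")
    if not np.all(np.isfinite(level1)):
        raise ValueError("level1 contains non-finite values")
    M = level1.shape[1]
    if M == 1:
        return np.array([1.0])
    a, _ = nnls(level1, targets)
    if a.sum() == 0.0:
        a = np.full(M, 1.0 / M)
    else:
        a = a / a.sum()
    if exact:
        res = minimize(
            lambda w: float(np.sum((targets - level1 @ w) ** 2)),
            a,
            jac=lambda w: -2.0 * level1.T @ (targets - level1 @ w),
            bounds=[(0.0, 1.0)] * M,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        a = np.clip(res.x, 0.0, None)
        a = a / a.sum()
    return a


def fit_superlearner(
    registry: LearnerRegistry,
    X: np.ndarray,
    y: np.ndarray,
    V: int = 10,
    seed: int = 0,
    exact_weights: bool = False,
    fit_id: str = "",
) -> EnsembleFit:
    """Level-1 generation, weight solve, and full-data refits."""
    level1, fold_of, kept = generate_cv_level1(registry, X, y, V=V, seed=seed)
    weights = solve_ensemble_weights(level1, y, exact=exact_weights)
    refits = {
        name: registry[name].fit(np.asarray(X, float), np.asarray(y, float), seed + 777 + mi)
        for mi, name in enumerate(kept)
    }
    return EnsembleFit(
        V=V,
        fold_of=fold_of,
        learner_names=kept,
        level1=level1,
        weights=weights,
        refits=refits,
        registry=registry,
        fit_id=fit_id,
    )


def compute_ers_sl(fit: EnsembleFit, X_new: np.ndarray, fit_id: str | None = None) -> ERSVector:
    """ERS_SL = sum_m a_m psi_m(E*) using the full-data refits."""
    X_new = np.asarray(X_new, dtype=float)
    values = np.zeros(len(X_new))
    for name, a in zip(fit.learner_names, fit.weights):
        if name not in fit.refits:
            raise KeyError(f"learner {name!r} has weight but no full-data refit")
        if a == 0.0:
            continue
        values += a * fit.registry[name].predict(fit.refits[name], X_new)
    return ERSVector(values=values, method="SL", fit_id=fit_id or fit.fit_id)


@dataclass
class ImportanceTable:
    """(SSE(-j) - SSE)/SSE per exposure; negative values allowed."""

    table: pd.DataFrame
    baseline_sse: float


def sl_variable_importance(
    registry: LearnerRegistry,
    X: np.ndarray,
    y: np.ndarray,
    exposure_names: list[str],
    V: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Leave-one-exposure-out importance with a shared fold split.

    SSE is the cross-validated sum of squared ensemble errors; reruns drop
    one exposure column at a time and reuse the baseline folds so the
    difference isolates the omission.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 exposures")
    if len(exposure_names) != p:
        raise ValueError("exposure_names must match X columns")
    fold_of = _make_folds(len(y), V, seed)

    def cv_sse(Xs: np.ndarray) -> float:
        level1, _, _ = generate_cv_level1(registry, Xs, y, V=V, seed=seed, fold_of=fold_of)
        a = solve_ensemble_weights(level1, y)
        return float(np.sum((y - level1 @ a) ** 2))

    sse = cv_sse(X)
    if sse <= 0:
        raise RuntimeError("baseline SSE is zero; importance undefined")
    rows = []
    for j in range(p):
        keep = [c for c in range(p) if c != j]
        try:
            sse_minus = cv_sse(X[:, keep])
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"importance rerun failed with {exposure_names[j]!r} omitted: {exc}"
            ) from exc
        rows.append(
            {"exposure": exposure_names[j], "importance": (sse_minus - sse) / sse}
        )
    return ImportanceTable(table=pd.DataFrame(rows), baseline_sse=sse)
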