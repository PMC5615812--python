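"""Elastic net and adaptive elastic net by cyclic coordinate descent.

The estimator minimizes

    sum_i (y_i - b0 - x_i' b)^2 + lam1 * sum_j w_j |b_j| + lam2 * sum_j f_j b_j^2

where ``w_j`` are adaptive L1 weights and ``f_j`` per-term penalty factors
(0 = unpenalized, used for covariates, which the penalty never shrinks).
The adaptive variant runs a first-stage plain elastic net tuned by K-fold
cross-validation over a (lam1, lam2) grid, sets the adaptive weights to
(|b_enet| + 1/n)^(-gamma), re-runs a weighted fit with its own CV over
lam1, and rescales the penalized coefficients by (1 + lam2/n) to undo the
double ridge shrinkage.  Large-sample SEs and p-values for the selected
terms come from a sandwich form on the selected submodel, treating the
selection as fixed (an approximation; post-selection inference caveats
apply).

The linear ERS is the weighted sum of the selected exposure terms only:
covariates and the intercept contribute nothing, so the score isolates
the mixture's contribution to the predicted outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import ERSVector
from .preprocessing import ExpandedDesign

__all__ = [
    "PenalizedFit",
    "fit_elastic_net",
    "fit_adaptive_elastic_net",
    "compute_ers_linear",
]


@dataclass
class PenalizedFit:
    """Penalized-regression solution over covariate + exposure terms."""

    terms: list[str]
    coef: np.ndarray
    intercept: float
    lam1: float
    lam2: float
    omega: np.ndarray  # adaptive L1 weights (0 for unpenalized terms)
    penalty_factors: np.ndarray
    term_types: dict[str, str]  # term -> main | interaction | covariate
    selected: list[str] = field(default_factory=list)
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    cv_records: pd.DataFrame | None = None
    fit_id: str = ""

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.terms)

    def coefficient_table(self) -> pd.DataFrame:
        """term, estimate, SE, p-value, type — the reporting artifact."""
        rows = []
        for t, b in zip(self.terms, self.coef):
            rows.append(
                {
                    "term": t,
                    "estimate": b,
                    "se": self.se.get(t, np.nan),
                    "p_value": self.pvalues.get(t, np.nan),
                    "type": self.term_types.get(t, "covariate"),
                }
            )
        return pd.DataFrame(rows)


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_solve(
    gram: np.ndarray,
    xty: np.ndarray,
    yty: float,
    lam1: float,
    lam2: float,
    w1: np.ndarray,
    w2: np.ndarray,
    beta: np.ndarray,
    tol: float = 1e-9,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Cyclic coordinate descent on the Gram form of the objective.

    ``w1``/``w2`` are the effective per-term L1/L2 weights (adaptive weight
    times penalty factor).  The objective is asserted non-increasing every
    sweep.  Scale of ``tol``: max absolute coefficient change per sweep.
    """
    p = len(xty)
    beta = beta.copy()
    d = np.diag(gram).copy()
    denom = d + lam2 * w2
    # columns with zero variance and no ridge cannot move
    movable = denom > 0
    q = gram @ beta  # maintained gradient piece

    def objective(b: np.ndarray, qv: np.ndarray) -> float:
        return (
            yty
            - 2.0 * b @ xty
            + b @ qv
            + lam1 * np.abs(b) @ w1
            + lam2 * (b * b) @ w2
        )

    prev_obj = objective(beta, q)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if not movable[j]:
                continue
            rho = xty[j] - q[j] + d[j] * beta[j]
            new = _soft_threshold(rho, 0.5 * lam1 * w1[j]) / denom[j]
            delta = new - beta[j]
            if delta != 0.0:
                beta[j] = new
                q += gram[:, j] * delta
                max_delta = max(max_delta, abs(delta))
        obj = objective(beta, q)
        if obj > prev_obj * (1 + 1e-10) + 1e-10:
            raise AssertionError(
                f"coordinate descent objective increased: {prev_obj} -> {obj}"
            )
        prev_obj = obj
        if max_delta < tol:
            return beta
    raise RuntimeError(
        f"coordinate descent did not converge in {max_sweeps} sweeps; "
        f"last max coefficient change {max_delta:.3e}"
    )


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lam1: float,
    lam2: float,
    penalty_factors: np.ndarray | None = None,
    l1_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_sweeps: int = 2000,
) -> tuple[np.ndarray, float]:
    """Single elastic-net solve; returns (coefficients, intercept).

    The intercept is unpenalized and handled by centering.  ``l1_weights``
    are the adaptive weights (default 1); the effective per-term penalties
    are ``lam1 * l1_weights * penalty_factors`` and
    ``lam2 * penalty_factors``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be non-negative")
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    if (pf < 0).any():
        raise ValueError("penalty factors must be non-negative")
    w = np.ones(p) if l1_weights is None else np.asarray(l1_weights, float)

    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    gram = Xc.T @ Xc
    xty = Xc.T @ yc
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    beta = _cd_solve(
        gram, xty, float(yc @ yc), lam1, lam2, w * pf, pf, beta, tol, max_sweeps
    )
    return beta, float(ym - xm @ beta)


def _lambda1_max(
    Xc: np.ndarray, yc: np.ndarray, w1: np.ndarray, free: np.ndarray
) -> float:
    """Smallest lam1 giving the all-zero penalized solution.

    Unpenalized columns stay in the model, so the outcome is first
    residualized on them.
    """
    if free.any():
        F = Xc[:, free]
        coef, *_ = np.linalg.lstsq(F, yc, rcond=None)
        r = yc - F @ coef
    else:
        r = yc
    pen = ~free
    grads = np.abs(Xc[:, pen].T @ r)
    wj = w1[pen]
    with np.errstate(divide="ignore"):
        vals = np.where(wj > 0, 2.0 * grads / np.where(wj > 0, wj, 1.0), np.inf)
    finite = vals[np.isfinite(vals)]
    if len(finite) == 0:
        raise ValueError("no penalized terms")
    return float(finite.max())


def _cv_path(
    X: np.ndarray,
    y: np.ndarray,
    lam1_seq: np.ndarray,
    lam2: float,
    pf: np.ndarray,
    w: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SE of CV squared prediction error along a lam1 path."""
    K = len(folds)
    errs = np.zeros((K, len(lam1_seq)))
    for k, (tr, va) in enumerate(folds):
        Xtr, ytr = X[tr], y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        gram = Xc.T @ Xc
        xty = Xc.T @ yc
        yty = float(yc @ yc)
        beta = np.zeros(X.shape[1])
        Xva, yva = X[va], y[va]
        for i, lam1 in enumerate(lam1_seq):
            beta = _cd_solve(gram, xty, yty, lam1, lam2, w * pf, pf, beta, tol)
            pred = (Xva - xm) @ beta + ym
            errs[k, i] = np.mean((yva - pred) ** 2)
    return errs.mean(axis=0), errs.std(axis=0, ddof=1) / np.sqrt(K)


def _pick(cv_mean: np.ndarray, cv_se: np.ndarray, rule: str) -> int:
    """Index into a descending lam1 path; ties resolve toward larger lam1."""
    best = int(np.argmin(cv_mean))  # argmin returns the first = largest lam1
    if rule == "1se":
        thresh = cv_mean[best] + cv_se[best]
        for i in range(best + 1):
            if cv_mean[i] <= thresh:
                return i
    return best


def fit_adaptive_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    terms: list[str],
    term_types: dict[str, str],
    penalty_free: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    gamma: float = 1.0,
    n_lambda1: int = 50,
    lambda1_decades: float = 4.0,
    lambda2_grid: np.ndarray | None = None,
    rule: str = "min",
    tol: float = 1e-8,
    fit_id: str = "",
) -> PenalizedFit:
    """Two-stage adaptive elastic net with K-fold CV tuning.

    ``penalty_free`` marks covariate columns (penalty factor 0).  Stage 1
    tunes (lam1, lam2) for a plain elastic net; stage 2 re-tunes lam1 with
    adaptive weights (|b1| + 1/n)^(-gamma) and lam2 carried over.  Final
    penalized coefficients are rescaled by (1 + lam2/n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(terms) != p:
        raise ValueError("terms must match design columns")
    if cv_folds < 2:
        raise ValueError("need at least 2 CV folds")
    free = np.asarray(penalty_free, dtype=bool)
    pf = np.where(free, 0.0, 1.0)

    if lambda2_grid is None:
        # sample-size-free ridge strengths; RSS scales with n
        lambda2_grid = n * np.array([0.0, 1e-4, 1e-3, 1e-2, 1e-1])

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [
        (np.setdiff1d(perm, part, assume_unique=False), part)
        for part in np.array_split(perm, cv_folds)
    ]

    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    ones = np.ones(p)

    lam1_max = _lambda1_max(Xc, yc, ones, free)
    lam1_seq = np.geomspace(lam1_max, lam1_max * 10.0 ** (-lambda1_decades), n_lambda1)

    records = []
    best = None  # (cv, lam2_idx, lam1_idx)
    for l2i, lam2 in enumerate(lambda2_grid):
        cv_mean, cv_se = _cv_path(X, y, lam1_seq, lam2, pf, ones, folds, tol)
        idx = _pick(cv_mean, cv_se, rule)
        records.append(
            pd.DataFrame(
                {
                    "stage": 1,
                    "lam1": lam1_seq,
                    "lam2": lam2,
                    "cv_mean": cv_mean,
                    "cv_se": cv_se,
                }
            )
        )
        if best is None or cv_mean[idx] < best[0]:
            best = (cv_mean[idx], l2i, idx)
    lam2_star = float(lambda2_grid[best[1]])
    lam1_star = float(lam1_seq[best[2]])

    beta1, _ = fit_elastic_net(X, y, lam1_star, lam2_star, pf, tol=tol)

    # adaptive stage requires some signal somewhere on the grid
    if np.all(beta1[~free] == 0.0):
        found = False
        for lam2 in lambda2_grid:
            btry, _ = fit_elastic_net(X, y, lam1_seq[-1], lam2, pf, tol=tol)
            if np.any(btry[~free] != 0.0):
                found = True
                beta1 = btry
                break
        if not found:
            raise RuntimeError(
                "signal too weak for adaptive stage: elastic net selects "
                "nothing at every grid point"
            )

    omega = np.where(free, 0.0, (np.abs(beta1) + 1.0 / n) ** (-gamma))
    w_stage2 = np.where(free, 1.0, omega)  # pf zeroes the free terms anyway

    lam1_max2 = _lambda1_max(Xc, yc, w_stage2, free)
    lam1_seq2 = np.geomspace(
        lam1_max2, lam1_max2 * 10.0 ** (-lambda1_decades), n_lambda1
    )
    cv_mean2, cv_se2 = _cv_path(X, y, lam1_seq2, lam2_star, pf, w_stage2, folds, tol)
    idx2 = _pick(cv_mean2, cv_se2, rule)
    records.append(
        pd.DataFrame(
            {
                "stage": 2,
                "lam1": lam1_seq2,
                "lam2": lam2_star,
                "cv_mean": cv_mean2,
                "cv_se": cv_se2,
            }
        )
    )
    lam1_final = float(lam1_seq2[idx2])

    beta2, _ = fit_elastic_net(
        X, y, lam1_final, lam2_star, pf, l1_weights=w_stage2, tol=tol
    )
    # undo the compound ridge shrinkage on the penalized terms
    beta_final = beta2.copy()
    beta_final[~free] *= 1.0 + lam2_star / n
    intercept = float(ym - xm @ beta_final)

    selected = [terms[j] for j in range(p) if (not free[j]) and beta_final[j] != 0.0]

    se, pvals = _submodel_inference(
        Xc, yc, beta_final, free, terms, selected, lam2_star, pf
    )

    return PenalizedFit(
        terms=list(terms),
        coef=beta_final,
        intercept=intercept,
        lam1=lam1_final,
        lam2=lam2_star,
        omega=omega,
        penalty_factors=pf,
        term_types=dict(term_types),
        selected=selected,
        se=se,
        pvalues=pvals,
        cv_records=pd.concat(records, ignore_index=True),
        fit_id=fit_id,
    )


def _submodel_inference(
    Xc: np.ndarray,
    yc: np.ndarray,
    beta: np.ndarray,
    free: np.ndarray,
    terms: list[str],
    selected: list[str],
    lam2: float,
    pf: np.ndarray,
) -> tuple[dict[str, float], dict[str, float]]:
    """Sandwich SEs on the selected submodel, selection treated as fixed."""
    sel_idx = [j for j, t in enumerate(terms) if t in set(selected) or free[j]]
    if not sel_idx:
        return {}, {}
    XA = Xc[:, sel_idx]
    r = yc - Xc @ beta
    info = XA.T @ XA + lam2 * np.diag(pf[sel_idx])
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return {}, {}
    meat = XA.T @ (XA * (r**2)[:, None])
    cov = info_inv @ meat @ info_inv
    se_arr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se, pvals = {}, {}
    for pos, j in enumerate(sel_idx):
        t = terms[j]
        s = float(se_arr[pos])
        se[t] = s
        if s > 0:
            z = beta[j] / s
            pvals[t] = float(2.0 * norm.sf(abs(z)))
        else:
            pvals[t] = float("nan")
    return se, pvals


def compute_ers_linear(fit: PenalizedFit, design: ExpandedDesign) -> ERSVector:
    """ERS_i = sum_j b_j E_i^j + sum_{k<l} b_kl E_i^k E_i^l.

    Only exposure terms (mains and interactions) contribute; covariates and
    the intercept are excluded so the score reflects the mixture alone.
    """
    exposure_terms = [
        t
        for t, b in zip(fit.terms, fit.coef)
        if fit.term_types.get(t) in ("main", "interaction") and b != 0.0
    ]
    missing = [t for t in exposure_terms if t not in design.names]
    if missing:
        raise KeyError(f"design is missing selected terms: {missing}")
    if not exposure_terms:
        values = np.zeros(design.X.shape[0])
    else:
        coefs = np.array(
            [fit.coef[fit.terms.index(t)] for t in exposure_terms]
        )
        values = design.columns(exposure_terms) @ coefs
    method = (
        "AENET-I"
        if any(fit.term_types.get(t) == "interaction" for t in fit.terms)
        else "AENET-M"
    )
    return ERSVector(values=values, method=method, fit_id=fit.fit_id)
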