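"""Held-out assessment of an ERS: continuous fit, binary discrimination,
and quintile risk stratification.

Metric conventions:

* the continuous model is ``y ~ ERS + Z`` fitted on the training half;
  MSE is its mean squared error on training, MSPE the mean squared
  prediction error on test, and PRESS the *sum* of squared prediction
  errors on the test half (the out-of-sample reading of PRESS, not the
  classical leave-one-out statistic);
* AUC is the rank (Mann-Whitney) statistic with tied scores averaged,
  bootstrap CI, and a permutation p-value comparing the covariate+ERS
  model's test AUC against the covariates-only base model, obtained by
  permuting the ERS within the test set and re-scoring with the
  training-fitted coefficients;
* quintile cutpoints come from the training ERS distribution
  (linear-interpolation quantiles); the reported OR contrasts the top
  against the bottom quintile on the test half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .core import ERSVector

__all__ = [
    "PerformanceReport",
    "continuous_metrics",
    "auc_rank",
    "auc_with_tests",
    "quintile_risk_stratification",
    "standardize_ers",
]


@dataclass
class PerformanceReport:
    method: str
    train_corr: float
    test_corr: float
    mse: float
    mspe: float
    press: float
    auc_base: float
    auc_base_ci: tuple[float, float]
    auc_full: float
    auc_full_ci: tuple[float, float]
    auc_perm_p: float
    quintile_or: float
    quintile_or_ci: tuple[float, float]
    quintile_cutpoints: tuple[float, ...]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in ("auc_base_ci", "auc_full_ci", "quintile_or_ci", "quintile_cutpoints"):
            d[k] = list(d[k])
        return d


def _design(ers: np.ndarray | None, Z: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if ers is not None:
        cols.append(np.asarray(ers, float))
    if Z is not None and np.size(Z):
        cols.append(np.asarray(Z, float))
    return np.column_stack(cols)


def continuous_metrics(
    y_train: np.ndarray,
    ers_train: np.ndarray,
    Z_train: np.ndarray | None,
    y_test: np.ndarray,
    ers_test: np.ndarray,
    Z_test: np.ndarray | None,
) -> dict[str, float]:
    """Correlations, MSE (train), MSPE and PRESS (test) of y ~ ERS + Z."""
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, float)
    ers_train = np.asarray(ers_train, float)
    ers_test = np.asarray(ers_test, float)
    if np.std(ers_train) == 0.0:
        raise ValueError("zero-variance ERS: correlation undefined")

    Xtr = _design(ers_train, Z_train, len(y_train))
    coef, *_ = np.linalg.lstsq(Xtr, y_train, rcond=None)
    fitted = Xtr @ coef
    Xte = _design(ers_test, Z_test, len(y_test))
    pred = Xte @ coef
    return {
        "train_corr": float(np.corrcoef(y_train, ers_train)[0, 1]),
        "test_corr": float(np.corrcoef(y_test, ers_test)[0, 1])
        if np.std(ers_test) > 0
        else float("nan"),
        "mse": float(np.mean((y_train - fitted) ** 2)),
        "mspe": float(np.mean((y_test - pred) ** 2)),
        "press": float(np.sum((y_test - pred) ** 2)),
    }


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-sum statistic, ties averaged."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for AUC")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _logit_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("logistic fit diverged: non-finite coefficients")
    return res.params


def auc_with_tests(
    y_train: np.ndarray,
    Z_train: np.ndarray | None,
    ers_train: np.ndarray,
    y_test: np.ndarray,
    Z_test: np.ndarray | None,
    ers_test: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Base (Z-only) and full (Z+ERS) test AUCs, bootstrap CIs, permutation p.

    Models are fitted on the training half; the permutation test shuffles
    the ERS within the test set and recomputes the AUC gain with the same
    fitted coefficients, so p in [1/(n_perm+1), 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y_test = np.asarray(y_test).astype(int)
    if len(np.unique(y_test)) < 2:
        raise ValueError("single-class test set")
    rng = np.random.default_rng(seed)

    Xb_tr = _design(None, Z_train, len(y_train))
    Xf_tr = _design(ers_train, Z_train, len(y_train))
    cb = _logit_fit(Xb_tr, np.asarray(y_train).astype(int))
    cf = _logit_fit(Xf_tr, np.asarray(y_train).astype(int))

    Xb_te = _design(None, Z_test, len(y_test))
    score_base = Xb_te @ cb
    ers_test = np.asarray(ers_test, float)

    def full_score(e: np.ndarray) -> np.ndarray:
        return _design(e, Z_test, len(y_test)) @ cf

    auc_base = auc_rank(y_test, score_base)
    auc_full = auc_rank(y_test, full_score(ers_test))
    observed_gain = auc_full - auc_base

    # bootstrap CIs over test subjects
    boot_b = np.empty(n_boot)
    boot_f = np.empty(n_boot)
    sf = full_score(ers_test)
    n = len(y_test)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        if len(np.unique(y_test[idx])) < 2:
            boot_b[b] = np.nan
            boot_f[b] = np.nan
            continue
        boot_b[b] = auc_rank(y_test[idx], score_base[idx])
        boot_f[b] = auc_rank(y_test[idx], sf[idx])
    ci_b = tuple(np.nanpercentile(boot_b, [2.5, 97.5]))
    ci_f = tuple(np.nanpercentile(boot_f, [2.5, 97.5]))

    hits = 0
    for _ in range(n_perm):
        gain = auc_rank(y_test, full_score(rng.permutation(ers_test))) - auc_base
        if gain >= observed_gain:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)

    return {
        "auc_base": auc_base,
        "auc_base_ci": ci_b,
        "auc_full": auc_full,
        "auc_full_ci": ci_f,
        "perm_p": p_perm,
    }


def quintile_risk_stratification(
    ers_train: np.ndarray,
    ers_test: np.ndarray,
    y_test: np.ndarray,
    Z_test: np.ndarray | None = None,
) -> dict:
    """OR (95% CI) for the top vs bottom training-quintile of ERS.

    Unadjusted (``Z_test=None``): closed-form cross-product ratio with a
    Woolf (log-scale Wald) CI — identical to the logistic MLE saturated in
    quintile indicators, without iteration error.  Adjusted: logistic
    model with quintile indicators (Q1 reference) plus covariates.
    """
    ers_train = np.asarray(ers_train, float)
    ers_test = np.asarray(ers_test, float)
    y_test = np.asarray(y_test).astype(int)
    if len(np.unique(ers_train)) < 5:
        raise ValueError("training ERS needs at least 5 distinct values")
    cut = np.quantile(ers_train, [0.2, 0.4, 0.6, 0.8])
    if not np.all(np.diff(cut) > 0):
        raise ValueError("quintile cutpoints are not strictly increasing")
    q = np.searchsorted(cut, ers_test, side="right")  # 0..4

    if (q == 0).sum() == 0 or (q == 4).sum() == 0:
        raise ValueError("empty extreme quintile in the test set")

    if Z_test is None:
        a = int(((q == 4) & (y_test == 1)).sum())  # Q5 cases
        b = int(((q == 4) & (y_test == 0)).sum())
        c = int(((q == 0) & (y_test == 1)).sum())  # Q1 cases
        d = int(((q == 0) & (y_test == 0)).sum())
        if min(a, b, c, d) == 0:
            raise ValueError("both outcome classes required in Q1 and Q5")
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
        return {"or": float(or_), "ci": (float(lo), float(hi)), "cutpoints": tuple(cut)}

    Qind = np.column_stack([(q == k).astype(float) for k in range(1, 5)])
    X = np.column_stack([np.ones(len(y_test)), Qind, np.asarray(Z_test, float)])
    params = _logit_fit(X, y_test)
    res = sm.Logit(y_test, X).fit(disp=0, start_params=params, maxiter=200)
    log_or = res.params[4]  # Q5 indicator
    se = res.bse[4]
    return {
        "or": float(np.exp(log_or)),
        "ci": (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))),
        "cutpoints": tuple(cut),
    }


def standardize_ers(ers: ERSVector | np.ndarray, reference: np.ndarray | None = None):
    """Z-score an ERS against a reference distribution (default: itself).

    The reference is normally the training-set ERS so train and test
    scores share a scale; one unit of the result is one reference SD.
    """
    values = ers.values if isinstance(ers, ERSVector) else np.asarray(ers, float)
    ref = values if reference is None else np.asarray(reference, float)
    sd = ref.std(ddof=1)
    if sd == 0.0:
        raise ValueError("reference SD is zero")
    z = (values - ref.mean()) / sd
    if isinstance(ers, ERSVector):
        return ERSVector(values=z, method=ers.method, fit_id=ers.fit_id)
    return z
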