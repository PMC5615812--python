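"""Gaussian kernel machine regression with Bayesian variable selection.

Model: Y_i = h(E_i) + Z_i' beta + eps_i, eps ~ N(0, sigma^2), with the
exposure surface h given a Gaussian-process prior whose covariance is
tau * K where K(E_i, E_i') = exp{-sum_j r_j (E_i^j - E_i'^j)^2} and
tau = lam * sigma^2.  Each exposure j carries an inclusion indicator
delta_j; r_j = 0 excludes the exposure from the surface.  The posterior
inclusion probability (PIP) of exposure j is the posterior frequency of
delta_j = 1.

Sampling integrates h out of the likelihood (Y ~ N(Z beta,
sigma^2 (I + lam K))), which markedly improves mixing of the kernel
scales; h is then recovered from its Gaussian conditional.  Priors: flat
(improper) on beta, weakly-informative inverse-gamma on sigma^2,
Gamma(1, 0.1) on lam, Bernoulli(0.5) on delta_j, Exponential(1) slab on
r_j | delta_j = 1 (birth proposals draw from the slab so the prior term
cancels).  ERS = posterior mean of h at the evaluation points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import ERSVector

__all__ = ["KernelModel", "gaussian_kernel_matrix", "fit_bkmr", "compute_ers_bkmr"]


def gaussian_kernel_matrix(
    E: np.ndarray, E2: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """K[i, i'] = exp{-sum_j r_j (E_i^j - E2_i'^j)^2}; exact evaluation."""
    E = np.atleast_2d(np.asarray(E, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("kernel scale parameters must be non-negative")
    if E.shape[1] != E2.shape[1] or E.shape[1] != len(r):
        raise ValueError("column counts of E, E2 and r must match")
    d2 = np.zeros((E.shape[0], E2.shape[0]))
    for j in range(E.shape[1]):
        if r[j] == 0.0:
            continue
        diff = E[:, j][:, None] - E2[:, j][None, :]
        d2 += r[j] * diff * diff
    return np.exp(-d2)


@dataclass
class KernelModel:
    """Retained MCMC draws and posterior summaries."""

    E_train: np.ndarray
    r_draws: np.ndarray  # (S, p)
    delta_draws: np.ndarray  # (S, p)
    beta_draws: np.ndarray  # (S, k)
    sigma2_draws: np.ndarray  # (S,)
    lam_draws: np.ndarray  # (S,)
    resid_draws: np.ndarray  # (S, n) y - Z beta per draw
    pip: np.ndarray  # (p,)
    h_train_mean: np.ndarray  # posterior mean of h at training points
    z_names: list[str]
    burn_in: int
    iterations: int

    @property
    def n_retained(self) -> int:
        return len(self.r_draws)


def _marginal_loglik(
    resid: np.ndarray, K: np.ndarray, sigma2: float, lam: float
) -> tuple[float, tuple]:
    """log N(resid; 0, sigma^2 (I + lam K)) and the Cholesky factor."""
    n = len(resid)
    V = np.eye(n) + lam * K
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        V += 1e-8 * np.eye(n)
        c, low = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(resid @ cho_solve((c, low), resid))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + quad / sigma2)
    return ll, (c, low)


def fit_bkmr(
    E: np.ndarray,
    Z_design: np.ndarray,
    y: np.ndarray,
    iterations: int = 2000,
    seed: int = 0,
    burn_frac: float = 0.5,
    rw_sd: float = 0.5,
    slab_rate: float = 1.0,
    max_exact_n: int = 1000,
    z_names: list[str] | None = None,
) -> KernelModel:
    """Metropolis-within-Gibbs sampler for the kernel machine model.

    ``Z_design`` is the encoded covariate matrix (no intercept column; one
    is added internally).  Above ``max_exact_n`` subjects a random training
    subsample is taken with a warning: every iteration costs O(n^3).
    """
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float)
    Z_design = np.asarray(Z_design, dtype=float)
    n, p = E.shape
    rng = np.random.default_rng(seed)

    if n > max_exact_n:
        warnings.warn(
            f"n={n} exceeds max_exact_n={max_exact_n}; fitting on a random "
            f"subsample of {max_exact_n} subjects"
        )
        sub = np.sort(rng.choice(n, size=max_exact_n, replace=False))
        E, y, Z_design = E[sub], y[sub], Z_design[sub]
        n = max_exact_n

    D = np.column_stack([np.ones(n), Z_design])
    k = D.shape[1]

    # cached per-dimension squared distances
    d2 = np.empty((p, n, n))
    for j in range(p):
        diff = E[:, j][:, None] - E[:, j][None, :]
        d2[j] = diff * diff

    def kernel(r: np.ndarray) -> np.ndarray:
        return np.exp(-np.tensordot(r, d2, axes=1))

    # initial state
    delta = np.ones(p, dtype=bool)
    r = np.full(p, 0.1)
    lam = 1.0
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    beta = coef
    resid = y - D @ beta
    sigma2 = float(resid @ resid) / max(n - k, 1)

    K = kernel(r * delta)
    ll, chol = _marginal_loglik(resid, K, sigma2, lam)

    burn_in = int(iterations * burn_frac)
    S = iterations - burn_in
    r_draws = np.zeros((S, p))
    delta_draws = np.zeros((S, p), dtype=int)
    beta_draws = np.zeros((S, k))
    sigma2_draws = np.zeros(S)
    lam_draws = np.zeros(S)
    resid_draws = np.zeros((S, n))
    h_mean_acc = np.zeros(n)

    def lam_logprior(x: float) -> float:
        return -0.1 * x  # Gamma(1, 0.1) up to a constant

    def slab_logprior(x: float) -> float:
        return -slab_rate * x  # Exponential(slab_rate) up to a constant

    for it in range(iterations):
        # (delta_j, r_j) updates
        for j in range(p):
            if not delta[j]:
                # birth: draw r_j from the slab (prior term cancels)
                r_new = rng.exponential(1.0 / slab_rate)
                r_prop = r.copy()
                r_prop[j] = r_new
                delta_prop = delta.copy()
                delta_prop[j] = True
                K_prop = kernel(r_prop * delta_prop)
                ll_prop, chol_prop = _marginal_loglik(resid, K_prop, sigma2, lam)
                if np.log(rng.random()) < ll_prop - ll:
                    delta, r, K, ll, chol = delta_prop, r_prop, K_prop, ll_prop, chol_prop
            else:
                if rng.random() < 0.5:
                    # death: set r_j to 0
                    delta_prop = delta.copy()
                    delta_prop[j] = False
                    K_prop = kernel(r * delta_prop)
                    ll_prop, chol_prop = _marginal_loglik(resid, K_prop, sigma2, lam)
                    if np.log(rng.random()) < ll_prop - ll:
                        delta, K, ll, chol = delta_prop, K_prop, ll_prop, chol_prop
                else:
                    # log-normal random walk refinement of r_j
                    r_prop = r.copy()
                    r_prop[j] = r[j] * np.exp(rw_sd * rng.standard_normal())
                    K_prop = kernel(r_prop * delta)
                    ll_prop, chol_prop = _marginal_loglik(resid, K_prop, sigma2, lam)
                    log_acc = (
                        ll_prop
                        - ll
                        + slab_logprior(r_prop[j])
                        - slab_logprior(r[j])
                        + np.log(r_prop[j])
                        - np.log(r[j])  # Jacobian of the log walk
                    )
                    if np.log(rng.random()) < log_acc:
                        r, K, ll, chol = r_prop, K_prop, ll_prop, chol_prop

        # lam: log-normal random walk
        lam_prop = lam * np.exp(rw_sd * rng.standard_normal())
        ll_prop, chol_prop = _marginal_loglik(resid, K, sigma2, lam_prop)
        log_acc = (
            ll_prop
            - ll
            + lam_logprior(lam_prop)
            - lam_logprior(lam)
            + np.log(lam_prop)
            - np.log(lam)
        )
        if np.log(rng.random()) < log_acc:
            lam, ll, chol = lam_prop, ll_prop, chol_prop

        # beta: GLS draw under the marginal covariance (flat prior)
        Vinv_D = cho_solve(chol, D)
        Vinv_y = cho_solve(chol, y)
        A = D.T @ Vinv_D / sigma2
        b = D.T @ Vinv_y / sigma2
        A_chol, low = cho_factor(A + 1e-12 * np.eye(k), lower=True)
        beta_hat = cho_solve((A_chol, low), b)
        L = np.linalg.cholesky(np.linalg.inv(A + 1e-12 * np.eye(k)))
        beta = beta_hat + L @ rng.standard_normal(k)
        resid = y - D @ beta

        # sigma^2: inverse-gamma conditional (weakly-informative prior)
        quad = float(resid @ cho_solve(chol, resid))
        sigma2 = (0.002 + quad) / rng.chisquare(0.002 + n)
        ll, chol = _marginal_loglik(resid, K, sigma2, lam)

        if it >= burn_in:
            s = it - burn_in
            r_eff = r * delta
            r_draws[s] = r_eff
            delta_draws[s] = delta.astype(int)
            beta_draws[s] = beta
            sigma2_draws[s] = sigma2
            lam_draws[s] = lam
            resid_draws[s] = resid
            # Rao-Blackwellized conditional mean of h at training points
            h_mean_acc += lam * (K @ cho_solve(chol, resid))

    pip = delta_draws.mean(axis=0)
    return KernelModel(
        E_train=E,
        r_draws=r_draws,
        delta_draws=delta_draws,
        beta_draws=beta_draws,
        sigma2_draws=sigma2_draws,
        lam_draws=lam_draws,
        resid_draws=resid_draws,
        pip=pip,
        h_train_mean=h_mean_acc / S,
        z_names=list(z_names or [f"z{j}" for j in range(Z_design.shape[1])]),
        burn_in=burn_in,
        iterations=iterations,
    )


def compute_ers_bkmr(
    model: KernelModel, E_new: np.ndarray, fit_id: str = "", thin: int = 1
) -> ERSVector:
    """Posterior mean of h(E_new), averaged over retained draws.

    Per draw the conditional mean is lam * K(E_new, E_train)
    (I + lam K)^{-1} (y - Z beta); ``thin`` subsamples draws to bound cost
    on large prediction sets.
    """
    E_new = np.atleast_2d(np.asarray(E_new, dtype=float))
    if E_new.shape[1] != model.E_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.E_train.shape[1]} "
            f"exposures, got {E_new.shape[1]}"
        )
    n = len(model.E_train)
    acc = np.zeros(len(E_new))
    draws = range(0, model.n_retained, thin)
    count = 0
    for s in draws:
        r = model.r_draws[s]
        lam = model.lam_draws[s]
        resid = model.resid_draws[s]
        K = gaussian_kernel_matrix(model.E_train, model.E_train, r)
        V = np.eye(n) + lam * K
        chol = cho_factor(V, lower=True)
        Kx = gaussian_kernel_matrix(E_new, model.E_train, r)
        acc += lam * (Kx @ cho_solve(chol, resid))
        count += 1
    return ERSVector(values=acc / count, method="BKMR", fit_id=fit_id)
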