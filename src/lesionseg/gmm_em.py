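"""Gaussian-mixture fitting by expectation-maximization, from first principles.

Model: each in-mask voxel's feature vector x (d-dimensional) is drawn from

    p(x) = sum_k pi_k N(x | mu_k, Sigma_k),      0 <= pi_k <= 1, sum_k pi_k = 1

with one mixture component per tissue class (K = 4 by default: WM, GM, CSF,
lesion).  N is the d-variate normal density with the standard normalizer
(2 pi)^(-d/2) |Sigma|^(-1/2).

EM alternates:

* E step: responsibilities gamma(z_nk) = pi_k N(x_n|mu_k,Sigma_k) /
  sum_j pi_j N(x_n|mu_j,Sigma_j), evaluated in log space with per-row
  max-subtraction;
* M step: weighted means, covariances about the new means, and weights
  N_k / N where N_k = sum_n gamma(z_nk);

until the absolute change in log-likelihood ln p(X|mu,Sigma,pi) =
sum_n ln sum_k pi_k N(x_n|mu_k,Sigma_k) drops below ``tol`` (default
1e-6 * N).  The log-likelihood trace is non-decreasing up to float round-off.

Numerical safeguards required by 25-dimensional voxel data: every covariance
is regularized by adding ``reg * I`` before factorization, and a component
whose effective count collapses is re-spread at the observation the current
model claims least confidently (lowest maximum responsibility).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .kmeans import kmeans_fit

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_MAX_ITER = 500
DEFAULT_REG = 1e-6
_COLLAPSE_COUNT = 1e-8
_WEIGHT_TOL = 1e-12
# Slack for the monotonicity guarantee: absolute floor plus a relative term
# that covers round-off accumulation when |loglik| is large.
_MONOTONE_SLACK = 1e-8


@dataclass
class GmmModel:
    """Fitted mixture: weights pi_k, means mu_k, covariances Sigma_k."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    K: int
    d: int
    loglik_trace: list[float]
    seed: int = 0
    converged: bool = False

    def check(self) -> None:
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL or np.any(self.weights < -_WEIGHT_TOL):
            raise ValueError(f"mixture weights invalid: {self.weights}")


@dataclass
class Responsibilities:
    """Posterior component memberships gamma(z_nk) and effective counts N_k."""

    gamma: np.ndarray  # (N, K)
    effective_counts: np.ndarray  # (K,)


def gaussian_log_density(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log of the d-variate normal density at each row of X, via Cholesky.

    Raises ``ValueError`` if sigma is not symmetric positive definite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    mu = np.asarray(mu, dtype=np.float64).ravel()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    d = mu.size
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"covariance is not symmetric positive definite: {e}") from e
    y = solve_triangular(L, (X - mu).T, lower=True)
    maha = np.einsum("dn,dn->n", y, y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def gaussian_density(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float | np.ndarray:
    """The d-variate normal density (2pi)^(-d/2) |Sigma|^(-1/2) exp(-maha/2)."""
    out = np.exp(gaussian_log_density(x, mu, sigma))
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def _component_log_densities(X: np.ndarray, model: GmmModel) -> np.ndarray:
    """(N, K) matrix of log pi_k + log N(x_n | mu_k, Sigma_k)."""
    N = X.shape[0]
    out = np.empty((N, model.K))
    with np.errstate(divide="ignore"):  # a zero weight maps to -inf cleanly
        logw = np.log(model.weights)
    for k in range(model.K):
        out[:, k] = logw[k] + gaussian_log_density(X, model.means[k], model.covariances[k])
    return out


def mixture_density(x: np.ndarray, model: GmmModel) -> float | np.ndarray:
    """p(x) = sum_k pi_k N(x | mu_k, Sigma_k)."""
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    vals = np.exp(logsumexp(_component_log_densities(X, model), axis=1))
    return float(vals[0]) if np.asarray(x).ndim == 1 else vals


def log_likelihood(X: np.ndarray, model: GmmModel) -> float:
    """ln p(X | mu, Sigma, pi), accumulated by log-sum-exp per observation."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return float(logsumexp(_component_log_densities(X, model), axis=1).sum())


def e_step(X: np.ndarray, model: GmmModel) -> Responsibilities:
    """Posterior responsibilities, normalized per row in log space."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    log_num = _component_log_densities(X, model)
    norm = logsumexp(log_num, axis=1)
    if np.any(~np.isfinite(norm)):
        raise ValueError(
            "degenerate model: some observation has zero density under every component"
        )
    gamma = np.exp(log_num - norm[:, None])
    return Responsibilities(gamma=gamma, effective_counts=gamma.sum(axis=0))


def m_step(
    X: np.ndarray, resp: Responsibilities, reg: float = DEFAULT_REG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximize the expected complete-data likelihood.

    Returns ``(weights, means, covariances)`` with each covariance computed
    about the *new* mean and regularized by ``reg * I``.  A component with a
    collapsed effective count is re-spread: its mean is set to the
    observation with the lowest maximum responsibility, its covariance to
    the regularized global covariance, and weights are renormalized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    N, d = X.shape
    gamma = resp.gamma
    K = gamma.shape[1]
    Nk = resp.effective_counts.copy()
    eye = reg * np.eye(d)

    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    weights = Nk / N
    collapsed = np.nonzero(Nk < _COLLAPSE_COUNT)[0]
    for k in range(K):
        if k in collapsed:
            continue
        means[k] = gamma[:, k] @ X / Nk[k]
        diff = X - means[k]
        covs[k] = (gamma[:, k] * diff.T) @ diff / Nk[k] + eye

    if collapsed.size:
        worst = int(np.argmin(gamma.max(axis=1)))
        global_cov = np.cov(X, rowvar=False).reshape(d, d) + eye
        for k in collapsed:
            logger.warning("component %d collapsed (N_k=%.3g); re-spread at row %d", k, Nk[k], worst)
            means[k] = X[worst]
            covs[k] = global_cov
            weights[k] = 1.0 / K
        weights = weights / weights.sum()
    return weights, means, covs


def _init_model(X, K, seed, init, reg, kmeans_labels=None):
    N, d = X.shape
    if init == "kmeans" or kmeans_labels is not None:
        if kmeans_labels is None:
            km = kmeans_fit(X, k=K, seed=seed)
            labels = km.assignments
        else:
            labels = np.asarray(kmeans_labels)
        gamma = np.zeros((N, K))
        gamma[np.arange(N), labels] = 1.0
        weights, means, covs = m_step(X, Responsibilities(gamma, gamma.sum(axis=0)), reg=reg)
    elif init == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(N, size=K, replace=False)
        means = X[idx].copy()
        covs = np.repeat(
            (np.cov(X, rowvar=False).reshape(d, d) + reg * np.eye(d))[None], K, axis=0
        )
        weights = np.full(K, 1.0 / K)
    else:
        raise ValueError(f"unknown init {init!r}")
    return GmmModel(
        weights=weights, means=means, covariances=covs, K=K, d=d,
        loglik_trace=[], seed=seed,
    )


def gmm_fit(
    X: np.ndarray,
    K: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float | None = None,
    init: str = "kmeans",
    reg: float = DEFAULT_REG,
    kmeans_labels: np.ndarray | None = None,
) -> tuple[GmmModel, Responsibilities, np.ndarray]:
    """Fit a K-component mixture by EM; returns (model, responsibilities, labels).

    ``init="kmeans"`` (default) seeds the mixture from one K-means fit —
    per-cluster means, covariances, and proportional weights; pre-computed
    cluster labels may be passed to reuse an existing K-means solution.
    ``init="random"`` uses K random observations and the global covariance.

    Convergence: ``|delta loglik| < tol`` with ``tol = 1e-6 * N`` by default.
    Hard labels are the argmax responsibility per row (ties to the lowest
    component index).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    N = X.shape[0]
    if N <= K:
        raise ValueError(f"need more observations ({N}) than components ({K})")
    if tol is None:
        tol = 1e-6 * N

    model = _init_model(X, K, seed, init, reg, kmeans_labels=kmeans_labels)
    model.check()
    model.loglik_trace.append(log_likelihood(X, model))

    resp = e_step(X, model)
    for it in range(1, max_iter + 1):
        weights, means, covs = m_step(X, resp, reg=reg)
        model = GmmModel(
            weights=weights, means=means, covariances=covs, K=K, d=model.d,
            loglik_trace=model.loglik_trace, seed=seed,
        )
        model.check()
        ll = log_likelihood(X, model)
        prev = model.loglik_trace[-1]
        if ll < prev - (_MONOTONE_SLACK + 1e-12 * abs(prev)):
            raise RuntimeError(f"log-likelihood decreased at iteration {it}: {prev} -> {ll}")
        model.loglik_trace.append(ll)
        logger.info("EM iteration %d: log-likelihood %.6f", it, ll)
        resp = e_step(X, model)
        if abs(ll - prev) < tol:
            model.converged = True
            break
    if not model.converged:
        logger.warning("EM hit max_iter=%d without meeting tol=%.3g", max_iter, tol)
    labels = np.argmax(resp.gamma, axis=1)
    return model, resp, labels
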