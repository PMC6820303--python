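"""Lloyd-style K-means over voxel feature space, written from first principles.

The objective is the distortion

    D = sum_i sum_{x in cluster i} ||x - C_i||^2

minimized by alternating nearest-center assignment and center recomputation
until the assignment stops changing.  Voxels are grouped into k = 4 clusters
(white matter, gray matter, CSF, and lesion when present); the clusters are
anonymous — naming them is the evaluation module's job.

Deterministic conventions (the algorithm statement leaves them open):

* initialization samples k *distinct* rows of X, uniformly over the distinct
  rows, without replacement, under the given seed;
* assignment ties break to the lowest cluster index;
* a cluster that empties is re-seeded at the row of X farthest from its
  stale center (logged);
* multi-restart: ``n_restarts`` independent seeded runs, best final
  distortion wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_MAX_ITER = 300
DEFAULT_RESTARTS = 10

# Slack for the per-iteration monotonicity check; Lloyd descent is exact in
# real arithmetic, this absorbs float round-off only.
_MONOTONE_SLACK = 1e-9


@dataclass
class KMeansModel:
    centers: np.ndarray  # (k, d)
    k: int
    assignments: np.ndarray  # (N,) in [0, k)
    cluster_sizes: np.ndarray  # (k,)
    distortion_trace: list[float]
    seed: int
    n_iter: int
    converged: bool

    @property
    def distortion(self) -> float:
        return self.distortion_trace[-1]


def kmeans_init(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k distinct rows of X, sampled uniformly without replacement under seed.

    Sampling over the *distinct* rows makes initialization invariant to row
    order and row duplication of X.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot pick {k} centers from {n} observations")
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] < k:
        raise ValueError(
            f"only {uniq.shape[0]} distinct rows for k={k} "
            f"({n - uniq.shape[0]} duplicates)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(uniq.shape[0], size=k, replace=False)
    return uniq[idx].copy()


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(N, k) squared Euclidean distances, computed from explicit differences.

    The difference form (not the expanded inner-product identity) keeps exact
    ties exact, so the documented tie-break is deterministic.
    """
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def assign_step(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment; ties break to the lowest cluster index."""
    if not np.all(np.isfinite(centers)):
        raise ValueError("centers must be finite")
    return np.argmin(_sq_distances(X, centers), axis=1)


def update_step(X: np.ndarray, assignments: np.ndarray, k: int,
                centers: np.ndarray | None = None) -> np.ndarray:
    """Recompute each center as the mean of its assigned rows.

    An empty cluster is re-seeded at the row of X farthest from that
    cluster's previous center (``centers`` must then be provided); the event
    is logged at WARNING.
    """
    X = np.asarray(X, dtype=np.float64)
    new_centers = np.empty((k, X.shape[1]), dtype=np.float64)
    for i in range(k):
        rows = X[assignments == i]
        if rows.shape[0] == 0:
            if centers is None:
                raise ValueError(f"cluster {i} is empty and no previous centers given")
            far = int(np.argmax(((X - centers[i]) ** 2).sum(axis=1)))
            logger.warning("cluster %d emptied; re-seeded at row %d", i, far)
            new_centers[i] = X[far]
        else:
            new_centers[i] = rows.mean(axis=0)
    return new_centers


def distortion(X: np.ndarray, centers: np.ndarray, assignments: np.ndarray) -> float:
    """Sum of squared Euclidean distances of each row to its assigned center."""
    diff = X - centers[assignments]
    return float(np.einsum("nd,nd->", diff, diff))


def _single_run(X, k, seed, max_iter):
    centers = kmeans_init(X, k, seed)
    trace: list[float] = []
    assignments = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_assignments = assign_step(X, centers)
        trace.append(distortion(X, centers, new_assignments))
        if len(trace) >= 2 and trace[-1] > trace[-2] + _MONOTONE_SLACK * max(1.0, trace[-2]):
            raise RuntimeError(
                f"distortion increased at iteration {it}: {trace[-2]} -> {trace[-1]}"
            )
        if assignments is not None and np.array_equal(new_assignments, assignments):
            converged = True
            assignments = new_assignments
            break
        assignments = new_assignments
        centers = update_step(X, assignments, k, centers=centers)
    sizes = np.bincount(assignments, minlength=k)
    return KMeansModel(
        centers=centers, k=k, assignments=assignments, cluster_sizes=sizes,
        distortion_trace=trace, seed=seed, n_iter=it, converged=converged,
    )


def kmeans_fit(
    X: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = DEFAULT_RESTARTS,
) -> KMeansModel:
    """Best-of-``n_restarts`` K-means fit (restart seeds ``seed, seed+1, ...``).

    Standardized features are recommended (not enforced).  Convergence means
    the assignment did not change between two consecutive iterations; runs
    that hit ``max_iter`` first are returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: KMeansModel | None = None
    for r in range(n_restarts):
        model = _single_run(X, k, (seed + r) % 2**31, max_iter)
        logger.info(
            "k-means restart %d/%d: distortion %.6g after %d iterations",
            r + 1, n_restarts, model.distortion, model.n_iter,
        )
        if best is None or model.distortion < best.distortion:
            best = model
    return best
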