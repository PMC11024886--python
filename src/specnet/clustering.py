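"""k-medoid (PAM) cluster grids on the similarity-derived distance matrix.

k-medoid clustering operates directly on an arbitrary precomputed
distance matrix, so its assignments are independent of any 2D projection
artifacts — it complements the t-SNE overview rather than deriving from
it.  The implementation is classical PAM: a deterministic greedy BUILD
initialisation followed by best-improvement SWAP steps until no swap
lowers the objective (sum of within-cluster distances to the medoid).
Determinism over speed: ties always break toward the lowest index, and
there is no random restart, so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "kmedoids", "kmedoid_grid", "DEFAULT_KS"]

DEFAULT_KS = (4, 8, 12, 16, 20)


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray  # per-feature cluster index in [0, k)
    medoids: np.ndarray  # k feature positions, ascending
    objective: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        self.medoids = np.asarray(self.medoids, dtype=np.intp)
        if self.medoids.size != self.k:
            raise ValueError("need exactly k medoids")
        if self.objective < 0:
            raise ValueError("objective must be non-negative")
        for c, m in enumerate(self.medoids):
            if self.labels[m] != c:
                raise ValueError(f"medoid {m} not labelled with its own cluster {c}")


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    return d


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid labels (ties -> lowest medoid position) and objective."""
    sub = d[:, medoids]  # n x k
    labels = np.argmin(sub, axis=1)  # argmin takes the first minimum:
    # medoids are kept sorted ascending, so ties go to the lowest position
    labels[medoids] = np.arange(medoids.size)  # a medoid owns its cluster
    # (its self-distance 0 always ties for the minimum)
    objective = float(sub[np.arange(d.shape[0]), labels].sum())
    return labels, objective


def _build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: start from the most central point, then repeatedly add
    the point giving the largest objective decrease (ties -> lowest index)."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        best = int(np.argmax(gain))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])
    return medoids


def kmedoids(d: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """PAM clustering of a precomputed distance matrix.

    ``seed`` is accepted for interface symmetry with the stochastic
    stages of the pipeline but unused: BUILD+SWAP with deterministic
    tie-breaking has no randomness.  The objective is asserted to be
    non-increasing across SWAP iterations.
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    medoids = np.sort(_build(d, k))
    _, objective = _assign(d, medoids)
    while True:
        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        in_set = np.zeros(n, dtype=bool)
        in_set[medoids] = True
        candidates = np.nonzero(~in_set)[0]
        for mi in range(k):
            trial = medoids.copy()
            for h in candidates:
                trial[mi] = h
                sub = d[:, trial]
                new_obj = sub.min(axis=1).sum()
                delta = new_obj - objective
                if delta < best_delta:
                    best_delta = delta
                    best_swap = (mi, int(h))
            trial[mi] = medoids[mi]
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = np.sort(medoids)
        _, new_objective = _assign(d, medoids)
        assert new_objective <= objective + 1e-9, "PAM objective increased"
        objective = new_objective
    labels, objective = _assign(d, medoids)
    return ClusterAssignment(k=k, labels=labels, medoids=medoids, objective=objective)


def kmedoid_grid(
    d: np.ndarray, ks: tuple[int, ...] = DEFAULT_KS, seed: int = 0
) -> list[ClusterAssignment]:
    """One PAM assignment per feasible k; infeasible ks are skipped with a
    warning, and an all-skipped grid is an error."""
    d = _check_distance_matrix(d)
    n = d.shape[0]
    out: list[ClusterAssignment] = []
    for k in ks:
        if not 2 <= k < n:
            logger.warning("k=%d skipped: needs 2 <= k < n (n=%d)", k, n)
            continue
        out.append(kmedoids(d, k, seed))
    if not out:
        raise ValueError("no k in the grid is feasible for this n")
    return out
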