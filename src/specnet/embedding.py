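"""2D t-SNE overview coordinates from the primary similarity matrix.

The overview layout is a t-SNE embedding of the similarity-derived
distance matrix (d = 1 - s).  Because t-SNE layouts are the stable
"mental map" everything else is overlaid on, the embedding is
initialised from the first two principal coordinates of the distance
matrix (classical MDS) rather than at random, so a fixed seed gives a
bit-stable layout.  A perplexity grid (usually 5-50) is run and each
embedding is scored by how well 2D distances preserve the
high-dimensional ones (Pearson and Spearman correlation of condensed
distances); the user picks, or the default rule picks the grid point
with maximal Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.manifold import TSNE

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingResult",
    "similarity_to_distance",
    "distance_preservation",
    "run_tsne_grid",
    "select_embedding",
    "DEFAULT_PERPLEXITIES",
]

DEFAULT_PERPLEXITIES = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # n x 2
    perplexity: float
    seed: int
    pearson_d: float
    spearman_d: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


def similarity_to_distance(m: SimilarityMatrix) -> np.ndarray:
    """d = 1 - s: symmetric, zero diagonal, values in [0, 1]."""
    d = 1.0 - m.scores
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def distance_preservation(
    high: np.ndarray, low: np.ndarray
) -> tuple[float, float]:
    """Pearson and Spearman correlation between two condensed distance lists.

    Degenerate (zero-variance) inputs correlate 1.0 when the lists are
    equal and 0.0 otherwise.
    """
    high = np.asarray(high, dtype=np.float64).ravel()
    low = np.asarray(low, dtype=np.float64).ravel()
    if high.shape != low.shape:
        raise ValueError("distance lists must have equal length")
    if np.array_equal(high, low):
        return 1.0, 1.0
    if np.std(high) == 0.0 or np.std(low) == 0.0:
        same = float(np.allclose(high, low))
        return same, same
    return (
        float(pearsonr(high, low).statistic),
        float(spearmanr(high, low).statistic),
    )


def _pcoa_init(d: np.ndarray) -> np.ndarray:
    """First two principal coordinates of a distance matrix, deterministic.

    Classical MDS double-centering; sign fixed so the largest-magnitude
    loading of each axis is positive; scaled to std 1e-4 as a t-SNE
    initialisation (small init keeps early exaggeration well-behaved).
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for axis in range(2):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    scale = coords.std()
    if scale > 0:
        coords = coords / scale * 1e-4
    return np.ascontiguousarray(coords)


def run_tsne_grid(
    m: SimilarityMatrix,
    perplexities: tuple[float, ...] = DEFAULT_PERPLEXITIES,
    seed: int = 0,
) -> list[EmbeddingResult]:
    """One t-SNE embedding per retained perplexity, with diagnostics.

    Perplexities >= (n - 1) / 3 are skipped with a warning (the
    neighborhood would span the whole data set); an empty retained grid
    is an error.  Deterministic for a fixed seed.
    """
    d = similarity_to_distance(m)
    n = m.n
    high = squareform(d, checks=False)
    init = _pcoa_init(d)
    results: list[EmbeddingResult] = []
    for perp in perplexities:
        if perp >= (n - 1) / 3:
            logger.warning(
                "perplexity %s skipped: requires n > %d (have n=%d)",
                perp, int(3 * perp + 1), n,
            )
            continue
        tsne = TSNE(
            n_components=2,
            perplexity=perp,
            metric="precomputed",
            init=init.copy(),
            random_state=seed,
            learning_rate="auto",
        )
        coords = tsne.fit_transform(d)
        low = pdist(coords)
        pear, spear = distance_preservation(high, low)
        results.append(EmbeddingResult(coords, float(perp), seed, pear, spear))
    if not results:
        raise ValueError("no perplexity in the grid is feasible for this n")
    return results


def select_embedding(
    results: list[EmbeddingResult], rule: str = "max_pearson"
) -> EmbeddingResult:
    """Pick one embedding from a grid.

    ``"max_pearson"`` (default): highest pearson_d, ties broken toward
    the lowest perplexity.  ``"manual:<p>"``: the result at perplexity p.
    """
    if not results:
        raise ValueError("no embedding results to select from")
    if rule == "max_pearson":
        return min(results, key=lambda r: (-r.pearson_d, r.perplexity))
    if rule.startswith("manual:"):
        target = float(rule.split(":", 1)[1])
        for res in results:
            if res.perplexity == target:
                return res
        raise ValueError(f"perplexity {target} not in the computed grid")
    raise ValueError(f"unknown selection rule: {rule!r}")
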