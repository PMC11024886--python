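"""Pairwise spectral similarity: the modified cosine score and matrix plumbing.

The modified cosine extends the plain spectral cosine by letting a
fragment pair match either directly (|mz_a - mz_b| <= tol) or shifted by
the precursor mass difference (|mz_a - mz_b - (prec_a - prec_b)| <= tol),
which links analogs that differ by a substituent mass.  Matching is a
greedy one-to-one pairing by descending intensity product — the
convention of the molecular-networking lineage this package follows —
so the score is a lower bound on the optimal-assignment cosine.

Externally computed score matrices (e.g. learned spectral similarities)
can be loaded from CSV and aligned to library order, standing in as the
primary score where available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "ScoreBundle",
    "modified_cosine",
    "pairwise_matrix",
    "load_matrix",
    "save_matrix",
    "to_edge_list",
]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n score matrix in [0, 1] with unit diagonal.

    Row/column order matches the :class:`~specnet.spectra.SpectrumLibrary`
    the scores were computed from; ``ids[i]`` names row i.
    """

    scores: np.ndarray
    ids: list[str]
    score_name: str = "modified_cosine"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match {n} ids"
            )
        if not np.allclose(self.scores, self.scores.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.scores), 1.0):
            raise ValueError("similarity matrix diagonal must be 1.0")
        if self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, positions: list[int]) -> np.ndarray:
        idx = np.asarray(positions, dtype=int)
        return self.scores[np.ix_(idx, idx)]


@dataclass
class ScoreBundle:
    """Primary score (drives the embedding) plus secondary score matrices."""

    primary: SimilarityMatrix
    secondaries: list[SimilarityMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sec in self.secondaries:
            if sec.ids != self.primary.ids:
                raise ValueError(
                    f"secondary {sec.score_name!r} id order differs from primary"
                )


def _candidate_pairs(
    a: Spectrum, b: Spectrum, tol: float
) -> list[tuple[float, int, int, int]]:
    """All (product, rule, i, j) candidates; rule 0 = direct, 1 = shifted.

    A pair eligible under both rules appears once, as direct (the products
    are identical, so the rule only matters for deterministic ordering).
    """
    diff = a.mz[:, None] - b.mz[None, :]
    direct = np.abs(diff) <= tol
    shifted = np.abs(diff - (a.precursor_mz - b.precursor_mz)) <= tol
    prod = a.intensity[:, None] * b.intensity[None, :]
    pairs = []
    for i, j in zip(*np.nonzero(direct | shifted)):
        rule = 0 if direct[i, j] else 1
        pairs.append((float(prod[i, j]), rule, int(i), int(j)))
    return pairs


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance: float = 0.1,
    mz_power: float = 0.0,
    intensity_power: float = 1.0,
    min_matches: int = 0,
) -> tuple[float, int]:
    """Modified cosine score between two spectra.

    Returns ``(score, n_matched_pairs)``; score = sum of matched
    intensity products divided by the product of the Euclidean peak-vector
    norms, clipped to [0, 1].  With ``min_matches`` set, a score built
    from fewer matched pairs is zeroed (off by default: minimum fragment
    overlap requirements make connectivity overly stringent).
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified cosine requires non-empty peak lists")
    wa = (a.mz ** mz_power) * (a.intensity ** intensity_power)
    wb = (b.mz ** mz_power) * (b.intensity ** intensity_power)
    if mz_power != 0.0 or intensity_power != 1.0:
        a = Spectrum(a.feature_id, a.precursor_mz, a.mz, wa, dict(a.metadata))
        b = Spectrum(b.feature_id, b.precursor_mz, b.mz, wb, dict(b.metadata))
    pairs = _candidate_pairs(a, b, fragment_tolerance)
    # greedy: descending product; ties prefer direct matches, then low indices
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    numerator = 0.0
    n_matched = 0
    for prod, _rule, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        numerator += prod
        n_matched += 1
    if min_matches and n_matched < min_matches:
        return 0.0, n_matched
    denom = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    score = numerator / denom if denom > 0 else 0.0
    return float(np.clip(score, 0.0, 1.0)), n_matched


def pairwise_matrix(
    lib: SpectrumLibrary,
    fragment_tolerance: float = 0.1,
    score_name: str = "modified_cosine",
    **kwargs,
) -> SimilarityMatrix:
    """All-pairs modified cosine matrix in library order."""
    n = len(lib)
    if n < 2:
        raise ValueError("pairwise matrix requires a library of size >= 2")
    scores = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s, _ = modified_cosine(lib[i], lib[j], fragment_tolerance, **kwargs)
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(scores, lib.ids, score_name)


def load_matrix(
    path: str | Path, ids: list[str], score_name: str = "external"
) -> SimilarityMatrix:
    """Load an externally computed score matrix from CSV and align it.

    The CSV carries feature ids as header row and index column, in any
    order; rows/columns are permuted to ``ids`` order.  Values outside
    [0, 1] are clipped with a warning; asymmetry beyond 1e-6 is an error;
    an off-unit diagonal is forced to 1.0 with a warning.
    """
    ids = [str(i) for i in ids]
    frame = pd.read_csv(path, index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    missing = sorted(set(ids) - set(frame.index)) or sorted(
        set(ids) - set(frame.columns)
    )
    if missing:
        raise ValueError(f"matrix at {path} is missing ids: {missing}")
    frame = frame.loc[ids, ids]
    scores = frame.to_numpy(dtype=np.float64)
    if np.abs(scores - scores.T).max() > 1e-6:
        raise ValueError(f"matrix at {path} is asymmetric beyond 1e-6")
    scores = (scores + scores.T) / 2.0
    if scores.min() < 0.0 or scores.max() > 1.0:
        logger.warning(
            "%s: %d value(s) outside [0, 1] clipped",
            path,
            int(np.sum((scores < 0) | (scores > 1))),
        )
        scores = np.clip(scores, 0.0, 1.0)
    if not np.allclose(np.diag(scores), 1.0):
        logger.warning("%s: diagonal forced to 1.0", path)
    np.fill_diagonal(scores, 1.0)
    return SimilarityMatrix(scores, ids, score_name)


def save_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    """Write a score matrix as CSV with ids as header row and index."""
    pd.DataFrame(m.scores, index=m.ids, columns=m.ids).to_csv(path)


def to_edge_list(m: SimilarityMatrix) -> pd.DataFrame:
    """Long-format (id_a, id_b, score) table over the strict upper triangle."""
    iu, ju = np.triu_indices(m.n, k=1)
    return pd.DataFrame(
        {
            "id_a": [m.ids[i] for i in iu],
            "id_b": [m.ids[j] for j in ju],
            "score": m.scores[iu, ju],
        }
    )
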