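"""Thresholded similarity networks and local topology views.

A network view is the edge set {(i, j) : s(i, j) >= threshold}, optionally
pruned by a mutual top-K rule: an edge survives only if it ranks within
both endpoints' K heaviest neighbors (the molecular-networking
convention; a single-sided variant keeps an edge that ranks in either
endpoint's list).  On top of a view sit the exploration primitives:
node-degree overlays, ego networks (induced subgraph within a hop
radius of a focal node), selection networks (edges inside vs leaving a
node selection), and the edge-weight distribution that guides threshold
choice.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "Edge",
    "NetworkView",
    "EgoView",
    "build_network",
    "ego_network",
    "selection_network",
    "degree_overlay",
    "edge_weight_distribution",
]


class Edge(NamedTuple):
    a: int  # feature position, a < b
    b: int
    weight: float


@dataclass
class NetworkView:
    n: int
    edges: list[Edge]
    threshold: float
    top_k: Optional[int] = None
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        seen = set()
        deg = np.zeros(self.n, dtype=np.intp)
        for e in self.edges:
            if not 0 <= e.a < e.b < self.n:
                raise ValueError(f"bad edge endpoints {(e.a, e.b)}")
            if (e.a, e.b) in seen:
                raise ValueError(f"duplicate edge {(e.a, e.b)}")
            if e.weight < self.threshold:
                raise ValueError(f"edge {(e.a, e.b)} below threshold")
            seen.add((e.a, e.b))
            deg[e.a] += 1
            deg[e.b] += 1
        self.degrees = deg

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for e in self.edges:
            adj[e.a].append(e.b)
            adj[e.b].append(e.a)
        return adj


@dataclass
class EgoView:
    ego: int
    hops: int
    nodes: list[int]
    edges: list[Edge]
    hop_of: dict[int, int]

    def __post_init__(self) -> None:
        if self.hop_of.get(self.ego) != 0:
            raise ValueError("ego must be at hop 0")
        if any(h > self.hops for h in self.hop_of.values()):
            raise ValueError("hop_of exceeds hop limit")
        node_set = set(self.nodes)
        if any(e.a not in node_set or e.b not in node_set for e in self.edges):
            raise ValueError("edge endpoint outside ego node set")


def _top_k_partners(
    neighbors: dict[int, list[tuple[float, int]]], k: int
) -> dict[int, set[int]]:
    """Per node, the set of partners ranked in its top k by weight
    (descending), ties broken toward the lower partner index."""
    top: dict[int, set[int]] = {}
    for node, lst in neighbors.items():
        ranked = sorted(lst, key=lambda t: (-t[0], t[1]))
        top[node] = {p for _, p in ranked[:k]}
    return top


def build_network(
    m: SimilarityMatrix,
    threshold: float = 0.7,
    top_k: Optional[int] = None,
    mutual: bool = True,
) -> NetworkView:
    """Threshold (inclusive, >=) the similarity matrix into a network view.

    With ``top_k`` set, an edge survives only if it ranks within both
    endpoints' top_k heaviest thresholded edges (``mutual=True``, the
    default) or within at least one endpoint's (``mutual=False``).
    An empty network is a valid result.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if top_k is not None and (top_k != math.inf and top_k < 1):
        raise ValueError("top_k must be >= 1")
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    keep = m.scores[iu, ju] >= threshold
    edges = [
        Edge(int(i), int(j), float(m.scores[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]
    if top_k is not None and top_k != math.inf:
        neighbors: dict[int, list[tuple[float, int]]] = {i: [] for i in range(n)}
        for e in edges:
            neighbors[e.a].append((e.weight, e.b))
            neighbors[e.b].append((e.weight, e.a))
        top = _top_k_partners(neighbors, int(top_k))
        if mutual:
            edges = [e for e in edges if e.b in top[e.a] and e.a in top[e.b]]
        else:
            edges = [e for e in edges if e.b in top[e.a] or e.a in top[e.b]]
    return NetworkView(
        n=n,
        edges=edges,
        threshold=threshold,
        top_k=None if top_k == math.inf else top_k,
    )


def ego_network(nv: NetworkView, ego: int, hops: int = 1) -> EgoView:
    """Induced subgraph within ``hops`` of the ego node (BFS layers).

    All view edges among the reached nodes are kept, not just the BFS
    tree, so the local topology is preserved.
    """
    if not 0 <= ego < nv.n:
        raise ValueError(f"ego position {ego} out of range")
    if hops < 1:
        raise ValueError("hops must be >= 1")
    adj = nv.adjacency()
    hop_of = {ego: 0}
    queue = deque([ego])
    while queue:
        node = queue.popleft()
        if hop_of[node] == hops:
            continue
        for nb in adj[node]:
            if nb not in hop_of:
                hop_of[nb] = hop_of[node] + 1
                queue.append(nb)
    nodes = sorted(hop_of)
    node_set = set(nodes)
    edges = [e for e in nv.edges if e.a in node_set and e.b in node_set]
    return EgoView(ego=ego, hops=hops, nodes=nodes, edges=edges, hop_of=hop_of)


def selection_network(
    nv: NetworkView, selection: Sequence[int]
) -> tuple[list[Edge], list[Edge]]:
    """Split the view's edges touching a selection into (internal, outward).

    internal: both endpoints selected; outward: exactly one endpoint
    selected.  The two lists are disjoint and together cover every edge
    incident to the selection.
    """
    sel = set(selection)
    if not sel:
        raise ValueError("selection must be non-empty")
    if any(not 0 <= s < nv.n for s in sel):
        raise ValueError("selection position out of range")
    internal = [e for e in nv.edges if e.a in sel and e.b in sel]
    outward = [e for e in nv.edges if (e.a in sel) != (e.b in sel)]
    return internal, outward


def degree_overlay(nv: NetworkView) -> np.ndarray:
    """Per-node incident-edge counts (the color-gradient overlay data)."""
    return nv.degrees.copy()


def edge_weight_distribution(
    m: SimilarityMatrix, bins: int = 20
) -> tuple[np.ndarray, np.ndarray, dict[float, float]]:
    """Histogram and quantiles of off-diagonal scores (upper triangle only).

    Returns (bin_edges, counts, quantiles) with quantiles at
    0.5, 0.9, 0.95 and 0.99 — the data behind the settings-panel plot
    that makes threshold choice an informed one.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    iu, ju = np.triu_indices(m.n, k=1)
    values = m.scores[iu, ju]
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    quantiles = {
        q: float(np.quantile(values, q)) for q in (0.5, 0.9, 0.95, 0.99)
    }
    return edges, counts, quantiles
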