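"""Session pipeline, configuration, metadata joining, and exporters.

``run_session`` executes the full import pipeline — read MGF, preprocess,
similarity (computed modified cosine or an externally supplied matrix),
t-SNE perplexity grid, k-medoid grid, thresholded network — and writes
all artifacts (coordinates, diagnostics, cluster labels, edge list,
GraphML, manifest) into an output directory.  Every CSV carries a header
comment with the tool version, parameters and seed; the run is
deterministic for a fixed seed, so a rerun reproduces the numeric
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .clustering import DEFAULT_KS, ClusterAssignment, kmedoid_grid
from .embedding import (
    DEFAULT_PERPLEXITIES,
    EmbeddingResult,
    run_tsne_grid,
    select_embedding,
    similarity_to_distance,
)
from .network import NetworkView, build_network
from .similarity import (
    SimilarityMatrix,
    load_matrix,
    pairwise_matrix,
    save_matrix,
    to_edge_list,
)
from .spectra import SpectrumLibrary, preprocess, read_mgf, write_mgf

logger = logging.getLogger(__name__)

__all__ = [
    "SessionConfig",
    "SessionResult",
    "run_session",
    "export_graphml",
    "join_metadata",
]


@dataclass
class SessionConfig:
    """Everything one pipeline run depends on, in one place."""

    mgf_path: str
    out_dir: str
    primary_matrix_path: Optional[str] = None
    metadata_path: Optional[str] = None
    fragment_tolerance: float = 0.1
    threshold: float = 0.7
    top_k: Optional[int] = None
    perplexities: tuple[float, ...] = DEFAULT_PERPLEXITIES
    ks: tuple[int, ...] = DEFAULT_KS
    seed: int = 0
    min_peaks: int = 2
    min_relative_intensity: float = 0.001
    mz_merge_tolerance: float = 0.01
    selection_rule: str = "max_pearson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.fragment_tolerance <= 0:
            raise ValueError("fragment_tolerance must be positive")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SessionConfig":
        """Parse a flat key=value config file ('#' starts a comment)."""
        values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        parsed: dict = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, val in values.items():
            if key not in hints:
                raise ValueError(f"unknown config key: {key!r}")
            if key in ("perplexities", "ks"):
                parsed[key] = tuple(float(x) if key == "perplexities" else int(x)
                                    for x in val.split(","))
            elif key in ("top_k",):
                parsed[key] = None if val.lower() in ("none", "") else int(val)
            elif key in ("seed", "min_peaks"):
                parsed[key] = int(val)
            elif key in ("fragment_tolerance", "threshold",
                         "min_relative_intensity", "mz_merge_tolerance"):
                parsed[key] = float(val)
            else:
                parsed[key] = val
        parsed.update(overrides)
        return cls(**parsed)


@dataclass
class SessionResult:
    library: SpectrumLibrary
    similarity: SimilarityMatrix
    embeddings: list[EmbeddingResult]
    selected: EmbeddingResult
    clusters: list[ClusterAssignment]
    network: NetworkView
    paths: dict[str, Path] = field(default_factory=dict)


def _header(cfg: SessionConfig) -> str:
    params = dataclasses.asdict(cfg)
    parts = [f"{k}={v}" for k, v in sorted(params.items())]
    return f"# specnet {__version__} | " + " ".join(parts) + "\n"


def _write_csv(frame: pd.DataFrame, path: Path, cfg: SessionConfig, **kwargs) -> None:
    with open(path, "w", newline="") as handle:
        handle.write(_header(cfg))
        frame.to_csv(handle, **kwargs)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"session stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - start)
            return out
        return inner
    return wrap


def run_session(cfg: SessionConfig) -> SessionResult:
    """Execute read -> preprocess -> similarity -> embedding grid ->
    cluster grid -> network, writing all artifacts under ``cfg.out_dir``.

    When ``primary_matrix_path`` is set, the loaded matrix wins over the
    computed modified cosine (logged); the modified cosine is still
    computed and saved as a secondary score in that case.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lib = _stage("read")(read_mgf)(cfg.mgf_path)
    lib = _stage("preprocess")(preprocess)(
        lib, cfg.min_peaks, cfg.min_relative_intensity, cfg.mz_merge_tolerance
    )
    if len(lib) < 2:
        raise RuntimeError("session stage 'preprocess' failed: fewer than 2 spectra survive")
    cosine = _stage("similarity")(pairwise_matrix)(lib, cfg.fragment_tolerance)
    if cfg.primary_matrix_path:
        logger.info("external primary matrix %s takes precedence over the "
                    "computed modified cosine", cfg.primary_matrix_path)
        primary = _stage("load_matrix")(load_matrix)(
            cfg.primary_matrix_path, lib.ids, "primary"
        )
    else:
        primary = cosine

    embeddings = _stage("embedding")(run_tsne_grid)(
        primary, cfg.perplexities, cfg.seed
    )
    selected = select_embedding(embeddings, cfg.selection_rule)
    distance = similarity_to_distance(primary)
    clusters = _stage("clustering")(kmedoid_grid)(distance, cfg.ks, cfg.seed)
    net = _stage("network")(build_network)(primary, cfg.threshold, cfg.top_k)

    paths: dict[str, Path] = {}

    paths["library"] = out / "library.mgf"
    write_mgf(lib, paths["library"])

    paths["similarity"] = out / "similarity_primary.csv"
    save_matrix(primary, paths["similarity"])
    if primary is not cosine:
        paths["modified_cosine"] = out / "similarity_modified_cosine.csv"
        save_matrix(cosine, paths["modified_cosine"])

    coords = pd.DataFrame(
        {"feature_id": lib.ids,
         "x": selected.coords[:, 0],
         "y": selected.coords[:, 1]}
    )
    paths["coordinates"] = out / "coordinates.csv"
    _write_csv(coords, paths["coordinates"], cfg, index=False)

    diag = pd.DataFrame(
        {"perplexity": [r.perplexity for r in embeddings],
         "pearson_d": [r.pearson_d for r in embeddings],
         "spearman_d": [r.spearman_d for r in embeddings],
         "selected": [r is selected for r in embeddings]}
    )
    paths["diagnostics"] = out / "tsne_diagnostics.csv"
    _write_csv(diag, paths["diagnostics"], cfg, index=False)

    label_rows = []
    for assign in clusters:
        for pos, lab in enumerate(assign.labels):
            label_rows.append((lib.ids[pos], assign.k, int(lab)))
    labels = pd.DataFrame(label_rows, columns=["feature_id", "k", "cluster"])
    paths["clusters"] = out / "clusters.csv"
    _write_csv(labels, paths["clusters"], cfg, index=False)

    edge_rows = pd.DataFrame(
        [(lib.ids[e.a], lib.ids[e.b], e.weight) for e in net.edges],
        columns=["id_a", "id_b", "score"],
    )
    paths["edges"] = out / "edges.csv"
    _write_csv(edge_rows, paths["edges"], cfg, index=False)

    paths["edge_list_full"] = out / "similarity_edge_list.csv"
    _write_csv(to_edge_list(primary), paths["edge_list_full"], cfg, index=False)

    meta = None
    if cfg.metadata_path:
        meta = _stage("metadata")(join_metadata)(lib, cfg.metadata_path)
        paths["metadata"] = out / "metadata.csv"
        _write_csv(meta, paths["metadata"], cfg)

    by_k = {assign.k: assign for assign in clusters}
    cluster_for_graph = by_k[min(by_k)]
    paths["graphml"] = out / "network.graphml"
    export_graphml(
        net, selected, paths["graphml"], ids=lib.ids,
        clusters=cluster_for_graph, meta=meta,
    )

    manifest = {
        "tool": "specnet",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "n_spectra": len(lib),
        "selected_perplexity": selected.perplexity,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return SessionResult(
        library=lib,
        similarity=primary,
        embeddings=embeddings,
        selected=selected,
        clusters=clusters,
        network=net,
        paths=paths,
    )


def export_graphml(
    nv: NetworkView,
    coords: EmbeddingResult,
    path: str | Path,
    ids: Optional[list[str]] = None,
    clusters: Optional[ClusterAssignment] = None,
    meta: Optional[pd.DataFrame] = None,
) -> None:
    """Write the network with layout and annotations as GraphML.

    Node attributes: id, x, y, degree, cluster (if given) and any
    metadata columns; edges carry the similarity as ``weight``.
    Re-importing reproduces edges and weights to 1e-6.
    """
    n = nv.n
    if coords.coords.shape[0] != n:
        raise ValueError("coordinate count does not match network size")
    if ids is not None and len(ids) != n:
        raise ValueError("id count does not match network size")
    if clusters is not None and clusters.labels.size != n:
        raise ValueError("cluster labels do not match network size")
    graph = nx.Graph()
    for pos in range(n):
        fid = ids[pos] if ids is not None else str(pos)
        attrs = {
            "feature_id": fid,
            "x": float(coords.coords[pos, 0]),
            "y": float(coords.coords[pos, 1]),
            "degree": int(nv.degrees[pos]),
        }
        if clusters is not None:
            attrs["cluster"] = int(clusters.labels[pos])
        if meta is not None and fid in meta.index:
            for col in meta.columns:
                attrs[str(col)] = str(meta.loc[fid, col])
        graph.add_node(fid, **attrs)
    for e in nv.edges:
        a = ids[e.a] if ids is not None else str(e.a)
        b = ids[e.b] if ids is not None else str(e.b)
        graph.add_edge(a, b, weight=float(e.weight))
    nx.write_graphml(graph, str(path))


def join_metadata(lib: SpectrumLibrary, table_path: str | Path) -> pd.DataFrame:
    """Left-join a metadata CSV onto the library's feature ids.

    Returns a frame indexed by feature_id in library order; features
    absent from the table get empty strings, table rows without a
    matching feature are logged.  A table without a feature_id column is
    an error.
    """
    table = pd.read_csv(table_path, dtype=str, comment="#").fillna("")
    if "feature_id" not in table.columns:
        raise ValueError(f"{table_path} has no feature_id column")
    table["feature_id"] = table["feature_id"].astype(str)
    dangling = set(table["feature_id"]) - set(lib.ids)
    if dangling:
        logger.warning(
            "%d metadata row(s) with no matching feature: %s",
            len(dangling), sorted(dangling)[:10],
        )
    table = table.drop_duplicates("feature_id").set_index("feature_id")
    joined = table.reindex(lib.ids).fillna("")
    joined.index.name = "feature_id"
    return joined
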