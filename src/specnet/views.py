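"""Derived inspection tables: augmap, fragmap, and mirror-plot pairing.

These are the data backing the quantitative "details on demand" panels:

* augmap — for a node selection, the primary-score submatrix plus, for
  each secondary score, the threshold-implied boolean adjacency mask
  (the same inclusive >= rule the network builder uses, so the two are
  bit-consistent by construction).
* fragmap — a multi-spectrum fragmentation-overlap grid: fragment m/z
  values (and optionally neutral losses, precursor minus fragment) are
  binned, occupied bins are sorted ascending and factorized to
  consecutive indices so the m/z axis carries no empty stretches, and
  each cell holds the relative intensity of that spectrum in that bin.
* mirror pair — the two spectra of a head-to-head comparison plot.

Only data tables are produced here; rendering belongs to a GUI layer
this package does not provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .similarity import ScoreBundle
from .spectra import Spectrum, SpectrumLibrary

__all__ = [
    "AugmapData",
    "FragmapData",
    "MirrorPair",
    "build_augmap",
    "build_fragmap",
    "mirror_pair",
]


@dataclass
class AugmapData:
    ids: list[str]
    primary_scores: np.ndarray  # m x m
    secondary_adjacency: dict[str, np.ndarray]  # score_name -> boolean mask
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        m = len(self.ids)
        if self.primary_scores.shape != (m, m):
            raise ValueError("primary submatrix shape mismatch")
        for name, mask in self.secondary_adjacency.items():
            if mask.shape != (m, m):
                raise ValueError(f"mask shape mismatch for {name!r}")
            if mask.dtype != bool:
                raise ValueError(f"mask for {name!r} must be boolean")
            if np.any(np.diag(mask)):
                raise ValueError(f"mask diagonal must be False for {name!r}")
            if not np.array_equal(mask, mask.T):
                raise ValueError(f"mask for {name!r} must be symmetric")


@dataclass
class FragmapData:
    spectrum_ids: list[str]
    bin_mz: np.ndarray  # representative m/z per occupied bin, ascending
    bin_index: np.ndarray  # 0..B-1, the rank of bin_mz
    intensity_grid: np.ndarray  # n_spectra x B, 0 where absent
    loss_mask: np.ndarray  # n_spectra x B booleans
    is_loss_bin: np.ndarray  # per-bin: occupied by loss entries only

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_mz) > 0):
            raise ValueError("bin_mz must be strictly ascending")
        if not np.array_equal(self.bin_index, np.arange(self.bin_mz.size)):
            raise ValueError("bin_index must be the ascending rank 0..B-1")
        if self.intensity_grid.min() < 0 or self.intensity_grid.max() > 1:
            raise ValueError("grid intensities must be in [0, 1]")


@dataclass
class MirrorPair:
    top: Spectrum
    bottom: Spectrum

    def __post_init__(self) -> None:
        if self.top.feature_id == self.bottom.feature_id:
            raise ValueError("mirror pair requires two distinct features")


def build_augmap(
    bundle: ScoreBundle,
    selection: Sequence[int],
    thresholds: dict[str, float],
) -> AugmapData:
    """Extract the augmap tables for a selection of feature positions.

    ``thresholds`` maps secondary score names to cutoffs in [0, 1]; a
    missing name falls back to the ``"default"`` entry (0.7 if absent).
    Exact numeric primary scores are preserved; adjacency is inclusive
    at the threshold (score >= cutoff), identical to network building.
    """
    sel = list(selection)
    if len(sel) < 2:
        raise ValueError("augmap requires a selection of size >= 2")
    default = thresholds.get("default", 0.7)
    for name, thr in thresholds.items():
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"threshold for {name!r} must be in [0, 1]")
    ids = [bundle.primary.ids[i] for i in sel]
    primary_sub = bundle.primary.submatrix(sel)
    adjacency: dict[str, np.ndarray] = {}
    used: dict[str, float] = {}
    for sec in bundle.secondaries:
        thr = thresholds.get(sec.score_name, default)
        sub = sec.submatrix(sel)
        mask = sub >= thr
        np.fill_diagonal(mask, False)
        adjacency[sec.score_name] = mask
        used[sec.score_name] = thr
    return AugmapData(
        ids=ids,
        primary_scores=primary_sub,
        secondary_adjacency=adjacency,
        thresholds=used,
    )


def build_fragmap(
    lib: SpectrumLibrary,
    selection: Sequence[int],
    bin_width: float = 0.01,
    min_intensity: float = 0.01,
    max_bins: int = 200,
    include_losses: bool = True,
    min_loss: float = 10.0,
    min_occurrence: int = 1,
) -> FragmapData:
    """Fragmentation-overlap grid for a multi-spectrum selection.

    Fragments with relative intensity >= ``min_intensity`` are assigned
    to bin floor(mz / bin_width).  With ``include_losses``, neutral
    losses (precursor m/z minus fragment m/z, kept when >= ``min_loss``
    Th) are binned onto the same axis and flagged in ``loss_mask``.
    Occupied bins are sorted ascending and factorized to consecutive
    indices; if more than ``max_bins`` bins are occupied, the bins with
    the highest total intensity across the selection are kept and then
    re-sorted.  ``min_occurrence`` optionally drops bins present in
    fewer spectra.  The representative m/z of a bin is the
    intensity-weighted mean of its member m/z values.
    """
    sel = list(selection)
    if len(sel) < 2:
        raise ValueError("fragmap requires a selection of size >= 2")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # entries: (bin_id, row, mz, intensity, is_loss)
    entries: list[tuple[int, int, float, float, bool]] = []
    for row, pos in enumerate(sel):
        spec = lib[pos].scaled()
        keep = spec.intensity >= min_intensity
        for mz, inten in zip(spec.mz[keep], spec.intensity[keep]):
            entries.append((int(mz // bin_width), row, float(mz), float(inten), False))
            if include_losses:
                loss = spec.precursor_mz - mz
                if loss >= min_loss:
                    entries.append(
                        (int(loss // bin_width), row, float(loss), float(inten), True)
                    )
    if not entries:
        raise ValueError("no fragments survive the intensity filter")
    bin_total: dict[int, float] = {}
    bin_rows: dict[int, set[int]] = {}
    for b, row, _mz, inten, _ in entries:
        bin_total[b] = bin_total.get(b, 0.0) + inten
        bin_rows.setdefault(b, set()).add(row)
    occupied = [b for b in bin_total if len(bin_rows[b]) >= min_occurrence]
    if not occupied:
        raise ValueError("no bin meets the min_occurrence requirement")
    if len(occupied) > max_bins:
        occupied = sorted(occupied, key=lambda b: (-bin_total[b], b))[:max_bins]
    occupied = sorted(occupied)
    bin_pos = {b: i for i, b in enumerate(occupied)}
    n_rows, n_bins = len(sel), len(occupied)
    grid = np.zeros((n_rows, n_bins))
    loss_mask = np.zeros((n_rows, n_bins), dtype=bool)
    has_fragment = np.zeros(n_bins, dtype=bool)
    mz_weight = np.zeros(n_bins)
    mz_sum = np.zeros(n_bins)
    for b, row, mz, inten, is_loss in entries:
        if b not in bin_pos:
            continue
        col = bin_pos[b]
        grid[row, col] = max(grid[row, col], inten)
        if is_loss:
            loss_mask[row, col] = True
        else:
            has_fragment[col] = True
        mz_sum[col] += mz * inten
        mz_weight[col] += inten
    return FragmapData(
        spectrum_ids=[lib[p].feature_id for p in sel],
        bin_mz=mz_sum / mz_weight,
        bin_index=np.arange(n_bins),
        intensity_grid=grid,
        loss_mask=loss_mask,
        is_loss_bin=~has_fragment,
    )


def mirror_pair(lib: SpectrumLibrary, id_a: str, id_b: str) -> MirrorPair:
    """The two spectra of a mirror plot, in requested (top, bottom) order."""
    if str(id_a) == str(id_b):
        raise ValueError("mirror pair requires two distinct feature ids")
    return MirrorPair(top=lib.get(id_a), bottom=lib.get(id_b))
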