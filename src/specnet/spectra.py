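"""Spectrum containers, MGF input/output, and preprocessing.

An MS/MS feature is a :class:`Spectrum`: a unique feature identifier, the
precursor mass-to-charge ratio (m/z, in Thomson), and a peak list of
(fragment m/z, intensity) tuples.  A :class:`SpectrumLibrary` is an ordered
collection of spectra; its order is load-bearing — row *i* of every
downstream similarity matrix, embedding and cluster assignment refers to
``library.spectra[i]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumLibrary",
    "read_mgf",
    "write_mgf",
    "preprocess",
]


class Peak(NamedTuple):
    """A single fragment peak: m/z in Thomson, positive relative intensity."""

    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One MS/MS feature.

    Peaks are stored as two parallel float64 arrays sorted strictly
    ascending by m/z; exact-duplicate m/z values are merged on
    construction (intensities summed).
    """

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_id = str(self.feature_id)
        self.precursor_mz = float(self.precursor_mz)
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if np.any(mz <= 0) or np.any(inten <= 0):
            raise ValueError("peak m/z and intensity values must be positive")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # merge exact m/z ties: intensities summed
        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        self.mz = mz
        self.intensity = inten

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def scaled(self) -> "Spectrum":
        """Copy with intensities scaled so the base peak is 1.0."""
        return Spectrum(
            self.feature_id,
            self.precursor_mz,
            self.mz.copy(),
            self.intensity / self.intensity.max(),
            dict(self.metadata),
        )


@dataclass
class SpectrumLibrary:
    """Ordered spectrum collection with a feature_id -> position index."""

    spectra: list[Spectrum]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {}
        for pos, spec in enumerate(self.spectra):
            if spec.feature_id in self.index:
                raise ValueError(f"duplicate feature_id: {spec.feature_id!r}")
            self.index[spec.feature_id] = pos

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, pos: int) -> Spectrum:
        return self.spectra[pos]

    @property
    def ids(self) -> list[str]:
        return [s.feature_id for s in self.spectra]

    def get(self, feature_id: str) -> Spectrum:
        try:
            return self.spectra[self.index[str(feature_id)]]
        except KeyError:
            raise KeyError(f"unknown feature_id: {feature_id!r}") from None


def _extract_feature_id(params: dict, fallback: int) -> tuple[str, str]:
    """FEATURE_ID takes precedence, then SCANS, then a sequential integer."""
    for key in ("feature_id", "scans"):
        if key in params and str(params[key]).strip():
            return str(params[key]).strip(), key.upper()
    return str(fallback), "sequential"


def read_mgf(path: str | Path) -> SpectrumLibrary:
    """Read an MGF file into a :class:`SpectrumLibrary`.

    File order is preserved.  Entries without a parseable PEPMASS are
    rejected with a logged warning; duplicate feature ids are a hard
    error; an empty file (no spectra at all) is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    n_entries = 0
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for entry in reader:
            n_entries += 1
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning(
                    "entry %d of %s has no PEPMASS; rejected", n_entries, path.name
                )
                continue
            feature_id, source = _extract_feature_id(params, n_entries)
            logger.debug("entry %d: feature_id %r from %s", n_entries, feature_id, source)
            metadata = {
                k: str(v)
                for k, v in params.items()
                if k not in ("pepmass", "feature_id", "scans")
            }
            spectra.append(
                Spectrum(
                    feature_id=feature_id,
                    precursor_mz=float(pepmass[0]),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    metadata=metadata,
                )
            )
    if n_entries == 0:
        raise ValueError(f"{path} contains no spectra")
    return SpectrumLibrary(spectra)


def write_mgf(lib: SpectrumLibrary, path: str | Path) -> None:
    """Write a library as MGF text; round-trips through :func:`read_mgf`
    losslessly (m/z and intensity to 6 decimal places)."""
    if len(lib) == 0:
        raise ValueError("refusing to write an empty library")
    entries = []
    for spec in lib:
        params = {"feature_id": spec.feature_id, "pepmass": spec.precursor_mz}
        params.update(spec.metadata)
        entries.append(
            {
                "m/z array": spec.mz,
                "intensity array": spec.intensity,
                "params": params,
            }
        )
    _mgf.write(
        entries,
        str(path),
        key_order=["feature_id", "pepmass"],
        fragment_format="%.6f %.6f",
        write_charges=False,
        use_numpy=True,
        file_mode="w",
    )


def _merge_close_peaks(
    mz: np.ndarray, inten: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy left-to-right merge of peaks within ``tol`` Th, iterated to a
    fixpoint so that no two surviving peaks are within tolerance."""
    while True:
        if mz.size < 2 or np.all(np.diff(mz) > tol):
            return mz, inten
        out_mz, out_in = [], []
        i = 0
        while i < mz.size:
            j = i + 1
            while j < mz.size and mz[j] - mz[j - 1] <= tol:
                j += 1
            w = inten[i:j]
            out_mz.append(float(np.average(mz[i:j], weights=w)))
            out_in.append(float(w.sum()))
            i = j
        mz = np.asarray(out_mz)
        inten = np.asarray(out_in)


def preprocess(
    lib: SpectrumLibrary,
    min_peaks: int = 2,
    min_relative_intensity: float = 0.001,
    mz_merge_tolerance: float = 0.01,
) -> SpectrumLibrary:
    """Normalise and filter every spectrum; drop spectra left too sparse.

    Per spectrum, in order: peaks within ``mz_merge_tolerance`` Th are
    merged (intensity-summed, intensity-weighted mean m/z), intensities
    are scaled so the base peak is 1.0, and peaks below
    ``min_relative_intensity`` are removed.  Spectra with fewer than
    ``min_peaks`` surviving peaks are dropped with a logged warning.
    The operation is idempotent for fixed parameters and preserves
    library order.
    """
    if min_peaks < 1:
        raise ValueError("min_peaks must be >= 1")
    if not 0 <= min_relative_intensity < 1:
        raise ValueError("min_relative_intensity must be in [0, 1)")
    kept: list[Spectrum] = []
    for spec in lib:
        mz, inten = _merge_close_peaks(spec.mz, spec.intensity, mz_merge_tolerance)
        inten = inten / inten.max()
        keep = inten >= min_relative_intensity
        mz, inten = mz[keep], inten[keep]
        if mz.size < min_peaks:
            logger.warning(
                "spectrum %r dropped: %d peak(s) after filtering (min_peaks=%d)",
                spec.feature_id,
                mz.size,
                min_peaks,
            )
            continue
        kept.append(
            Spectrum(spec.feature_id, spec.precursor_mz, mz, inten, dict(spec.metadata))
        )
    return SpectrumLibrary(kept)
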