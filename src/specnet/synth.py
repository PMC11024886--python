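"""Synthetic spectral libraries with planted molecular families.

Emulates the group structure spectral networking is built to recover:
each family shares an exact fragment backbone core, members carry a
precursor "analog" mass offset applied to the precursor and the
non-shared backbone peaks (mimicking substituent mass differences, which
exercises the precursor-shifted matching of the modified cosine), plus
uniform-random noise peaks.  No attempt is made at realistic
fragmentation chemistry or isotope patterns — the generator plants a
known family label per spectrum so that similarity, embedding,
clustering and network code can be tested without external data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import Spectrum, SpectrumLibrary, write_mgf

__all__ = ["FamilySpec", "generate_library", "write_fixture"]


@dataclass
class FamilySpec:
    """Recipe for one planted molecular family.

    shared_fraction is the fraction of backbone peaks every member
    inherits exactly (to float precision); the rest are shifted by the
    member's analog offset, drawn uniformly in ±analog_shift_range Th.
    """

    n_members: int = 10
    backbone_peaks: int = 12
    shared_fraction: float = 0.7
    precursor_base: float = 400.0
    analog_shift_range: float = 20.0
    noise_peaks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.backbone_peaks < 1:
            raise ValueError("n_members and backbone_peaks must be >= 1")
        if not 0 < self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in (0, 1]")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")


def _member_spectrum(
    fam_idx: int,
    member_idx: int,
    fam: FamilySpec,
    backbone_mz: np.ndarray,
    backbone_int: np.ndarray,
    n_shared: int,
    rng: np.random.Generator,
) -> Spectrum:
    # member 0 is the family prototype (zero analog shift)
    shift = 0.0 if member_idx == 0 else float(
        rng.uniform(-fam.analog_shift_range, fam.analog_shift_range)
    )
    mz = backbone_mz.copy()
    mz[n_shared:] += shift
    inten = backbone_int.copy()
    if fam.noise_peaks > 0:
        precursor = fam.precursor_base + shift
        noise_mz = rng.uniform(50.0, precursor, size=fam.noise_peaks)
        # log-uniform intensities in [0.01, 1]
        noise_int = np.exp(rng.uniform(math.log(0.01), 0.0, size=fam.noise_peaks))
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return Spectrum(
        feature_id=f"F{fam_idx}_{member_idx}",
        precursor_mz=fam.precursor_base + shift,
        mz=mz,
        intensity=inten,
    )


def generate_library(
    families: list[FamilySpec], seed: int = 0
) -> tuple[SpectrumLibrary, list[int]]:
    """Generate a library with planted families; returns (library, labels).

    Deterministic for a fixed seed: every random stream is keyed on
    (seed, family seed, member index).  labels[i] is the family index of
    library.spectra[i].
    """
    if not families:
        raise ValueError("at least one family is required")
    spectra: list[Spectrum] = []
    labels: list[int] = []
    for fam_idx, fam in enumerate(families):
        fam_rng = np.random.default_rng([seed, fam.seed, fam_idx])
        backbone_mz = np.sort(
            fam_rng.uniform(50.0, fam.precursor_base - 50.0, size=fam.backbone_peaks)
        )
        backbone_int = fam_rng.uniform(0.1, 1.0, size=fam.backbone_peaks)
        n_shared = max(1, math.ceil(fam.shared_fraction * fam.backbone_peaks))
        for member_idx in range(fam.n_members):
            member_rng = np.random.default_rng([seed, fam.seed, fam_idx, member_idx])
            spectra.append(
                _member_spectrum(
                    fam_idx, member_idx, fam, backbone_mz, backbone_int,
                    n_shared, member_rng,
                )
            )
            labels.append(fam_idx)
    return SpectrumLibrary(spectra), labels


def write_fixture(
    lib: SpectrumLibrary,
    labels: list[int],
    mgf_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write the fixture MGF and the (feature_id, family) labels CSV."""
    if len(labels) != len(lib):
        raise ValueError("labels length must match library size")
    write_mgf(lib, mgf_path)
    with open(labels_path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["feature_id", "family"])
        for spec, lab in zip(lib, labels):
            writer.writerow([spec.feature_id, lab])
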