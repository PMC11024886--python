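import numpy as np
import pytest

import specnet as sn


def make_spectrum(feature_id, precursor_mz, peaks, **metadata):
    mz, inten = zip(*peaks)
    return sn.Spectrum(feature_id, precursor_mz, np.array(mz), np.array(inten),
                       dict(metadata))


@pytest.fixture
def mkspec():
    return make_spectrum


@pytest.fixture(scope="session")
def family_library():
    """3 planted families x 5 members, preprocessed; returns (lib, labels)."""
    fams = [
        sn.FamilySpec(n_members=5, seed=i, precursor_base=280.0 + 70 * i)
        for i in range(3)
    ]
    lib, labels = sn.generate_library(fams, seed=11)
    return sn.preprocess(lib), labels


@pytest.fixture(scope="session")
def fixture50(tmp_path_factory):
    """5 families x 10 members written to disk; returns (mgf_path, labels_path)."""
    fams = [
        sn.FamilySpec(n_members=10, seed=i, precursor_base=300.0 + 60 * i)
        for i in range(5)
    ]
    lib, labels = sn.generate_library(fams, seed=1)
    root = tmp_path_factory.mktemp("fixture50")
    mgf, lab = root / "library.mgf", root / "labels.csv"
    sn.write_fixture(lib, labels, mgf, lab)
    return mgf, lab


@pytest.fixture(scope="session")
def similarity50(fixture50):
    """Preprocessed library + modified cosine matrix of the 50-spectrum fixture."""
    mgf, _ = fixture50
    lib = sn.preprocess(sn.read_mgf(mgf))
    return lib, sn.pairwise_matrix(lib)


def random_spectrum(rng, n_peaks, precursor=None):
    precursor = precursor or float(rng.uniform(200, 500))
    mz = np.sort(rng.uniform(50, precursor, size=n_peaks))
    inten = rng.uniform(0.05, 1.0, size=n_peaks)
    return sn.Spectrum(f"r{rng.integers(1 << 30)}", precursor, mz, inten)


@pytest.fixture
def rand_spec():
    return random_spectrum
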