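import numpy as np
import pytest

from twodir import (
    NoiseSpec,
    hinact_preset,
    make_spectrum,
)
from twodir.peakfit import extract_matrix


@pytest.fixture(scope="session")
def preset():
    modes, truth = hinact_preset()
    return modes, truth


@pytest.fixture(scope="session")
def clean_spectrum():
    spec, peaks = make_spectrum()
    return spec, peaks


@pytest.fixture(scope="session")
def clean_extraction(clean_spectrum, preset):
    """Noise-free synth -> fit -> assemble, shared across tests (slow step)."""
    spec, _ = clean_spectrum
    modes, _ = preset
    matrix, fits, audit = extract_matrix(spec, modes)
    return matrix, fits, audit


@pytest.fixture(scope="session")
def noisy_extraction(preset):
    """Same pipeline with 5% additive noise at a fixed seed."""
    modes, _ = preset
    spec, _ = make_spectrum(noise=NoiseSpec(0.05, seed=1))
    matrix, fits, audit = extract_matrix(spec, modes)
    return matrix, fits, audit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
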