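import numpy as np
import pytest

import toxprofiler as tp


@pytest.fixture(scope="session")
def planted_library():
    """Noise-free 5-class library: class members have identical profiles."""
    return tp.generate_library(
        n_compounds=200, n_classes=5, n_assays=12, n_bits=64,
        signal_strength=1.0, seed=42,
    )


@pytest.fixture(scope="session")
def noisy_library():
    return tp.generate_library(
        n_compounds=200, n_classes=5, n_assays=12, n_bits=64,
        signal_strength=0.0, seed=42,
    )


@pytest.fixture(scope="session")
def clean_titration():
    """Noise-free potent activator: AC50 1 uM, efficacy 80%, slope 1."""
    return tp.generate_plate_set(
        true_ac50=1e-6, true_efficacy=80.0, hill_slope=1.0,
        noise_sd=0.0, seed=7,
    )[0]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
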