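import numpy as np
import pytest

from specfx import SyntheticSpec, gen_spectrum_effect


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset (10 batches x 70 peaks)."""
    return gen_spectrum_effect(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Small zero-noise dataset for exhaustive planted-peak checks.

    Eight peaks, three planted per endpoint, no assay noise and no batch
    factor, more batches than the study for a well-conditioned check of the
    'planted peaks score on top' property.
    """
    spec = SyntheticSpec(n_batches=30, n_peaks=8, n_active=3, noise_sd=0.0,
                         batch_effect_sd=0.0, endpoints=("frap",), seed=5)
    return gen_spectrum_effect(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
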