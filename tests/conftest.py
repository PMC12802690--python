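import numpy as np
import pytest

from cortexmeth import synthetic_data


@pytest.fixture(scope="session")
def small_dataset():
    """60 sites x 40 samples with all three trajectory classes."""
    return synthetic_data.simulate_dataset(
        n_sites=60, n_samples=40, class_mix=(0.5, 0.3, 0.2), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
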