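import numpy as np
import pytest

import faceimprint as fi


@pytest.fixture(scope="session")
def small_config():
    return fi.SyntheticConfig(
        n_individuals=30, m_attributes=6, n_active=3, image_size=16, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Images, attributes and ground-truth prototypes of a 90-image set."""
    return fi.make_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
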