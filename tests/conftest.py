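import numpy as np
import pytest

import rorprep as rp


@pytest.fixture(scope="session")
def centroids():
    return rp.load_centroids()


@pytest.fixture(scope="session")
def cohort(centroids):
    """Default simulated cohort (study-sized, seeded) with ground truth."""
    config = rp.SimConfig(seed=7)
    macro, bulk, truth = rp.simulate_cohort(config, centroids)
    return config, macro, bulk, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
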