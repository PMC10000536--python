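import numpy as np
import pytest

from eagleseg import PhantomSpec, make_phantom
from eagleseg.histogram import N_LEVELS


@pytest.fixture(scope="session")
def uniform_hist():
    return np.full(N_LEVELS, 1.0 / N_LEVELS)


@pytest.fixture(scope="session")
def two_spike_hist():
    p = np.zeros(N_LEVELS)
    p[0] = p[255] = 0.5
    return p


@pytest.fixture(scope="session")
def phantom_pair():
    """Default phantom image with its ground-truth tumor mask (seed 0)."""
    return make_phantom(PhantomSpec(seed=0))


def random_histogram(rng, sparse=False):
    """A valid normalized 256-bin histogram, optionally with many empty bins."""
    if sparse:
        p = np.zeros(N_LEVELS)
        idx = rng.choice(N_LEVELS, size=rng.integers(1, 20), replace=False)
        p[idx] = rng.random(idx.size)
    else:
        p = rng.random(N_LEVELS)
    return p / p.sum()
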