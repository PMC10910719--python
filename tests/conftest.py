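import numpy as np
import pytest

import scploidy as sp


@pytest.fixture(scope="session")
def small_grid():
    """1000-bin synthetic grid shared by cheap tests."""
    return sp.make_grid(1000, seed=11)


@pytest.fixture(scope="session")
def tiny_grid():
    """200-bin grid for very small tests."""
    return sp.make_grid(200, n_chroms=4, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
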