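import numpy as np
import pytest

from nesbr3 import IndeterminacyInterval, NesBr3Params, load_dataset


@pytest.fixture(scope="session")
def covid():
    return load_dataset("covid_nl")


@pytest.fixture(scope="session")
def relief():
    return load_dataset("relief")


@pytest.fixture(scope="session")
def indet_05():
    return IndeterminacyInterval(0.0, 0.05)


@pytest.fixture(scope="session")
def param_grid():
    """Parameter grid spanning small-to-moderate shapes at several indeterminacies."""
    grid = []
    for lam in (0.5, 1.0, 2.0, 5.0):
        for theta in (0.9, 2.0, 3.5, 6.0):
            for indet in (0.0, 0.05, 0.3):
                grid.append(NesBr3Params(lam, theta, indet))
    return grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240511)
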