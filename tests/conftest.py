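import numpy as np
import pytest

import somatoprf as sp
from somatoprf.synthetic import default_designs


@pytest.fixture(scope="session")
def space():
    return sp.HandSpace()


@pytest.fixture(scope="session")
def between_fwd(space):
    return sp.build_design(space, "between_digit", "forward")


@pytest.fixture(scope="session")
def between_bwd(between_fwd):
    return between_fwd.reversed()


@pytest.fixture(scope="session")
def within_fwd(space):
    return sp.build_design(space, "within_digit", "forward")


@pytest.fixture(scope="session")
def session_designs(space):
    """The full session: forward+backward runs of both dimensions."""
    return default_designs(space)


@pytest.fixture(scope="session")
def hrf():
    return sp.DoubleGammaHRF()


@pytest.fixture(scope="session")
def noiseless_dataset(space):
    """Default synthetic dataset, noiseless (120 voxels, 4 runs)."""
    return sp.simulate_dataset(space=space, seed=11)


def pearson(a, b):
    return float(np.corrcoef(np.asarray(a), np.asarray(b))[0, 1])
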