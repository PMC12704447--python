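import numpy as np
import pytest

from chromvqa import lattice, likelihood, oracle


@pytest.fixture(scope="session")
def universe3():
    return oracle.enumerate_universe(3)


@pytest.fixture(scope="session")
def universe4():
    return oracle.enumerate_universe(4)


@pytest.fixture(scope="session")
def universe6():
    return oracle.enumerate_universe(6)


@pytest.fixture(scope="session")
def hairpin4():
    """Four-bead fold with contacts (0,3) and (1,3)."""
    s = lattice.SpinString.from_iterable(4, [1, 1, -1, -1, -1, -1])
    return lattice.decode_spins(s)


@pytest.fixture(scope="session")
def straight4():
    """Four collinear beads (all spins +1)."""
    s = lattice.SpinString.from_iterable(4, [1, 1, 1, 1, 1, 1])
    return lattice.decode_spins(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_cfg():
    return likelihood.ModelConfig()
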