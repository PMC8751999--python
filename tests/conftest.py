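import numpy as np
import pytest

from motiflattice import FccLattice, MotifSequence, make_block_sequence


@pytest.fixture(scope="session")
def lat4():
    return FccLattice((4, 4, 4))


@pytest.fixture(scope="session")
def lat6():
    return FccLattice((6, 6, 6))


@pytest.fixture(scope="session")
def ab():
    return MotifSequence("AB")


@pytest.fixture(scope="session")
def block24_3():
    return make_block_sequence(24, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
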