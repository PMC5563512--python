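import numpy as np
import pytest

from unzipfoot import (
    DesignSpec,
    HairpinSequence,
    NNModel,
    SSDNAModel,
    design_sequence,
    initial_valid_sequence,
)


@pytest.fixture(scope="session")
def nn():
    return NNModel()


@pytest.fixture(scope="session")
def ss():
    return SSDNAModel()


@pytest.fixture(scope="session")
def covering_seq():
    """A valid all-tetramer 170-bp stem (coverage only, no flattening)."""
    return initial_valid_sequence(DesignSpec(seed=5, steps=0))


@pytest.fixture(scope="session")
def designed():
    """A fully designed (annealed + polished) flat hairpin with trajectory."""
    seq, traj = design_sequence(DesignSpec(seed=0))
    return seq, traj


@pytest.fixture(scope="session")
def designed_seq(designed):
    return designed[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stem(rng, n):
    return HairpinSequence("".join(rng.choice(list("ACGT"), size=n)))
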