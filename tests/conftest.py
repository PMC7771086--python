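import numpy as np
import pytest

from subsites.fixtures import FixtureSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default groove fixture: (structure, catalytic annotation, ground truth)."""
    return make_toy_complex(FixtureSpec())


@pytest.fixture(scope="session")
def toy4():
    """Short 4-mer substrate covering S4..S1 only."""
    return make_toy_complex(FixtureSpec(peptide_length=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
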