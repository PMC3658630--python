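import numpy as np
import pytest

from ardrapipe import (generate_community, generate_reference_sequences,
                       default_gut_design)

from tests_support import make_pattern


@pytest.fixture(scope="session")
def small_counts():
    """A 30-clone library with a realistic rank-abundance shape."""
    return np.array([12, 6, 4, 3, 2, 1, 1, 1])


@pytest.fixture(scope="session")
def gradient_design():
    """Default 3-fish x 3-compartment gradient study (seeded)."""
    return default_gut_design(seed=11)


@pytest.fixture(scope="session")
def sequenced_community():
    """A 12-taxon community with reference sequences attached."""
    comm = generate_community(12, "geometric", k=0.7, seed=5)
    return generate_reference_sequences(comm, amplicon_len=1445,
                                        between_taxon_divergence=0.15, seed=6)


@pytest.fixture
def pattern_factory():
    return make_pattern
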