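import numpy as np
import pytest

from clunio import ClonalParams, GeneticParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_clonal():
    """Short clonal run parameters for fast behavioural tests."""
    return ClonalParams(generations=60, seed=7)


@pytest.fixture
def quick_genetic():
    """Short genetic run parameters for fast behavioural tests."""
    return GeneticParams(generations=60, seed=7)
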