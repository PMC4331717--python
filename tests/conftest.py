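import numpy as np
import pytest

from phenofuse import Prioritizer
from phenofuse.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def signal_world():
    """Default planted world: modules drive both phenotype and gene similarity."""
    return generate_world(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def null_world():
    """World with no planted effect and pure-noise gene similarities."""
    return generate_world(SyntheticConfig(effect_b=0.0,
                                          source_reliabilities=(0.0, 0.0, 0.0),
                                          seed=11))


@pytest.fixture(scope="session")
def wide_null_world():
    """Null world with enough diseases that sampled non-associated pairs are
    nearly independent (few scored genes share a phenotype vector)."""
    return generate_world(SyntheticConfig(n_diseases=400, effect_b=0.0,
                                          source_reliabilities=(0.0, 0.0, 0.0),
                                          seed=17))


@pytest.fixture(scope="session")
def wide_null_prioritizer(wide_null_world):
    w = wide_null_world
    return Prioritizer(w.phenotype, w.sources, w.assoc, null_size=2500, seed=5)


@pytest.fixture(scope="session")
def signal_prioritizer(signal_world):
    w = signal_world
    return Prioritizer(w.phenotype, w.sources, w.assoc, null_size=1000, seed=1)


@pytest.fixture(scope="session")
def null_prioritizer(null_world):
    w = null_world
    return Prioritizer(w.phenotype, w.sources, w.assoc, null_size=2500, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
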