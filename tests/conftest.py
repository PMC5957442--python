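import numpy as np
import pytest

from exofoot.simulate import SimConfig, default_models, simulate


@pytest.fixture(scope="session")
def registry():
    return default_models()


@pytest.fixture(scope="session")
def sigma70_small():
    """A 100-promoter sigma70 run shared by read-only tests."""
    return simulate(SimConfig(preset="sigma70", n_promoters=100, seed=11,
                              with_sequence=False))


@pytest.fixture(scope="session")
def crp_small():
    """A 100-promoter activating-Crp run (with genome sequence and sites)."""
    return simulate(SimConfig(preset="crp_activating", n_promoters=100, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
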