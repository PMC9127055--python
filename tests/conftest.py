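import numpy as np
import pytest

from eegnets.core import DEFAULT_PROTOCOL, make_montage
from eegnets.gsvd import concatenate_group, group_svd, zstandardize
from eegnets.synthetic import default_networks, simulate_group


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def short_protocol():
    """Protocol with the full 4-segment structure at 1/5 length (2.6 min)."""
    return DEFAULT_PROTOCOL.scaled(0.2)


@pytest.fixture(scope="session")
def tiny_protocol():
    return DEFAULT_PROTOCOL.scaled(0.1)


@pytest.fixture(scope="session")
def small_networks():
    return default_networks(5)


@pytest.fixture(scope="session")
def small_group(small_networks, short_protocol):
    """6 subjects x 2 conditions of synthetic EEG with 5 planted networks."""
    pairs = simulate_group(6, small_networks, short_protocol, rate=256,
                           noise_level=0.3, seed=42)
    return [r for p in pairs for r in p]


@pytest.fixture(scope="session")
def small_decomposition(small_group):
    """Standardized group matrix and its exact SVD."""
    G = concatenate_group([zstandardize(r) for r in small_group])
    R = group_svd(G, method="exact")
    return G, R


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
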