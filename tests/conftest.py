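import numpy as np
import pytest

from v2texture.texture_sensitivity import ModulationProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(n_neurons: int, n_families: int, seed: int = 0) -> ModulationProfile:
    """A fully valid random modulation profile with entries in (-1, 1)."""
    gen = np.random.default_rng(seed)
    matrix = gen.uniform(-0.9, 0.9, size=(n_neurons, n_families))
    return ModulationProfile(M_matrix=matrix, valid_mask=np.ones(n_neurons, dtype=bool))


@pytest.fixture
def small_profile():
    return random_profile(12, 5, seed=7)
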