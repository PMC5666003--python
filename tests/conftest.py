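import numpy as np
import pytest

from dermapol import polcore


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """Random physical Mueller matrix: depolarizer ∘ retarder ∘ diattenuator."""
    M = polcore.linear_retarder(rng.uniform(0, 180), rng.uniform(-90, 90))
    M = polcore.isotropic_depolarizer(rng.uniform(0, 0.9)) @ M
    M = M @ polcore.linear_diattenuator(rng.uniform(0, 0.9), rng.uniform(-90, 90))
    return M


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def physical_matrices(rng):
    def make(n: int) -> np.ndarray:
        return np.stack([random_physical_mueller(rng) for _ in range(n)])

    return make
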