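import numpy as np
import pytest

from skinspeckle import (
    PatchSimParams,
    SpeckleSimParams,
    simulate_skin_patch_pair,
    simulate_speckle_sequence,
)


@pytest.fixture(scope="session")
def small_speckle_params():
    return SpeckleSimParams(height=32, width=32, n_frames=60, rho=0.7, seed=7)


@pytest.fixture(scope="session")
def small_speckle(small_speckle_params):
    return simulate_speckle_sequence(small_speckle_params)


@pytest.fixture(scope="session")
def patch_pair():
    return simulate_skin_patch_pair(PatchSimParams(con=30.9, seed=3))


@pytest.fixture
def constant_patch():
    return np.full((65, 65, 3), 100, dtype=np.uint8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
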