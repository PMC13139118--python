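import numpy as np
import pytest

from neutrack.simulate import (SimConfig, clean_separated_config,
                               scripted_scenario, simulate_sequence)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy random simulation shared across tests."""
    return simulate_sequence(SimConfig(
        image_size=(256, 256), n_frames=12, n_cells_initial=8, seed=42))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, well-separated simulation (6 cells, 10 frames)."""
    return simulate_sequence(clean_separated_config(6, 10, seed=3))


@pytest.fixture(scope="session")
def merge_fixture():
    return scripted_scenario("two_cells_cross_merge_split")
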