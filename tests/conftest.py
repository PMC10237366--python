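import numpy as np
import pytest

from cooccur.synthetic import SimConfig, generate_env_stack, simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A light study system used across tests (40x40 km, 4 layers, 8 species)."""
    return SimConfig(
        grid_nx=40,
        grid_ny=40,
        n_layers=4,
        n_species=8,
        n_motifs_true=2,
        seasonal_shift=0.3,
        migrant_fraction=0.25,
        detection_rate=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_system(small_config):
    """(stack, niches, occurrences, regions) for the small study system."""
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_env_stack(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
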