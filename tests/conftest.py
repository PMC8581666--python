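import pytest

from mirclust import examples
from mirclust.simulate import SimConfig, UtrParams, simulate_all


@pytest.fixture(scope="session")
def study_tree():
    return examples.species_tree()


@pytest.fixture(scope="session")
def study_presence():
    return examples.presence_matrix()


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset reused across tests (fixed seed)."""
    config = SimConfig(
        rng_seed=3,
        utr_params=UtrParams(n_genes=80, planted_per_member=5, utr_length=300),
    )
    return simulate_all(config)
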