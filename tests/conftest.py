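import pytest

from scaffkit.simulator import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_chromosomes=3, chromosome_length=300_000,
                     n_scaffolds=12, n_markers=96, n_individuals=120,
                     pair_coverage=12.0)


@pytest.fixture(scope="session")
def small_ds(small_config):
    """Small clean dataset for unit tests."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def error_ds():
    """Dataset with every planted error kind."""
    cfg = SimConfig(seed=5, n_chromosomes=3, chromosome_length=800_000,
                    n_scaffolds=33, n_markers=260, n_individuals=180,
                    n_chimera=2, n_excision=2, n_adjacent_split=2,
                    n_gap_missize=2, pair_coverage=20.0)
    return simulate_dataset(cfg)
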