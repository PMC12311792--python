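import pytest

from dpcseq.simulate import SimulationConfig, build_toy_genome


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study configuration: small genome and repeat panels so
    simulation-backed tests run in seconds while keeping every mechanism."""
    return SimulationConfig(
        seed=11,
        genome_length=600_000,
        n_chromosomes=2,
        repeat_length=3_000,
        n_control_genes=5,
        control_gene_length=600,
        repeat_read_depth=150.0,
        repeat_error_rate=0.0,
        n_replicates=2,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_toy_genome(small_config)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=5)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return build_toy_genome(default_config)
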