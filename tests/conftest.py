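import pytest

from srnapipe.simulate import SimulationConfig, generate_genome, plant_srna_loci


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Default study-design configuration with a fixed seed."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_genome(sim_config):
    """(genome, genes) for the default design; session-scoped: read-only."""
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def planted(sim_config, synthetic_genome):
    """(genome, genes, loci) with the default 20 loci per class."""
    genome, genes = synthetic_genome
    loci = plant_srna_loci(genes, sim_config)
    return genome, genes, loci
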