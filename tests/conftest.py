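import pytest

from pegtrace.config import SimConfig
from pegtrace.genome import make_genome, make_snp_map, make_truth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, genes_per_chromosome=15)


@pytest.fixture(scope="session")
def genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def snps(genome, small_config):
    return make_snp_map(genome, small_config.snp_density, small_config.seed)


@pytest.fixture(scope="session")
def truth(genome, small_config):
    return make_truth(genome, small_config)
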