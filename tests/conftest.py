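import pytest

from oxbalance import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=400, n_snps=200, n_genes=100,
                            n_pathways=10, pathway_size_range=(25, 30),
                            seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """Default-scale study: n=2000, 900 SNPs, 50 pathways, one causal."""
    return simulate_study(SimulationConfig())
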