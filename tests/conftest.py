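import numpy as np
import pytest

from egenscore import PipelineConfig, SimConfig
from egenscore.simulate import simulate_study


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A desk-sized study: 3 genes, 30 cis SNPs each, realistic LD blocks."""
    return SimConfig(
        n_train=120,
        n_panel=150,
        n_external=80,
        n_genes=3,
        snps_per_gene=30,
        block_size=5,
        within_block_rho=0.8,
        n_causal=1,
        h2=0.5,
        missing_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    return simulate_study(small_sim_config)


@pytest.fixture()
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
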