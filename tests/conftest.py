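import dataclasses

import pytest

from primedchip.analysis import analyze_dataset
from primedchip.simulate import SimConfig, simulate_dataset


SMALL_CONFIG = SimConfig(
    n_genes=300, n_chroms=3, mean_count=100.0, tf_mean_count=50.0, seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene dataset for fast structural tests."""
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_sim():
    """The default study design (2000 genes, 10% primed) at a fixed seed."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full end-to-end analysis of the default dataset (computed once)."""
    return analyze_dataset(default_sim)


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim.truth.set_index("gene_id")


def small_config(**overrides) -> SimConfig:
    return dataclasses.replace(SMALL_CONFIG, **overrides)
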