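import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from bloomsex.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def bloom(default_config):
    """One simulated bloom (counts + truth) shared across tests."""
    return simulate_counts(default_config)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A smaller bloom for end-to-end pipeline tests."""
    return SimulationConfig(
        n_genes=700,
        cluster_sizes=(90, 100, 60, 55, 45, 40),
        marker_gene_count=8,
        seed=2,
    )
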