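import numpy as np
import pytest

from rohmap.pedigree import Individual, Pedigree
from rohmap.synthetic_pedigree import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Default synthetic dataset: first-cousin parents, 3 affected and 2
    unaffected children, 100 Mb genome, planted causal missense variant."""
    return simulate(default_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same study design with 0.5% genotyping error injected into the panel."""
    return simulate(SimulationConfig(seed=23, genotyping_error_rate=0.005))


def nuclear_family(n_affected=3, n_unaffected=2):
    """A plain (non-consanguineous) nuclear family for filter tests."""
    members = [
        Individual("FA", sex="male", affected="unaffected"),
        Individual("MO", sex="female", affected="unaffected"),
    ]
    for i in range(n_affected):
        members.append(Individual(f"P{i + 1}", "FA", "MO", affected="affected"))
    for i in range(n_unaffected):
        members.append(Individual(f"S{i + 1}", "FA", "MO", affected="unaffected"))
    return Pedigree(members)


@pytest.fixture
def family():
    return nuclear_family()
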