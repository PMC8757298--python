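"""Shared fixtures: small simulated DO cohorts reused across test modules."""

import numpy as np
import pytest

from outbredqtl import (
    SimulationConfig,
    loco_kinship,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=120,
        chromosomes=(("1", 100.0, 40), ("2", 100.0, 40)),
        recomb_rate=0.05,
        n_mrna=40,
        n_mirna=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genotypes, expression panel and ground truth for a desk-scale cohort."""
    return simulate_dataset(small_config, interaction_scale=0.4)


@pytest.fixture(scope="session")
def small_kinship(small_dataset):
    geno, _, _ = small_dataset
    return loco_kinship(geno)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
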