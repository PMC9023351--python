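"""Shared fixtures: seeded generators and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from paleowgd.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-WGD dataset shared by read-only tests."""
    config = SimulationConfig(
        n_species=6,
        n_families=60,
        birth_rate=0.05,
        loss_rate=0.05,
        retention=0.5,
        fractionation=0.2,
        codons_per_gene=60,
        seed=101,
    )
    return simulate_dataset(config)
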