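"""Shared fixtures: a small, fast synthetic cohort and SA budgets sized for
unit tests.  Session scope keeps the numba kernels warm across tests."""

import numpy as np
import pytest

from pathdrp import SAConfig, SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_samples=60,
        n_genes=120,
        n_pathways=5,
        pathway_size_range=(8, 14),
        n_planted_subpathways=3,
        planted_size_range=(3, 5),
        delta=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def fast_sa() -> SAConfig:
    return SAConfig(iterations=600, restarts=2, permutations=99,
                    max_subpathways=3, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
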