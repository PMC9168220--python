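import logging

import numpy as np
import pytest

import scnet
from scnet.pipeline import build_group_tables, residualize_cohort

logging.getLogger("scnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort: 12 cortical + 3 non-cortical regions."""
    cfg = scnet.CohortConfig(n_cortical=12, n_noncortical=3, seed=7)
    return scnet.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    return residualize_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_group_tables(small_residuals):
    return {g: build_group_tables(small_residuals, g) for g in scnet.cohort.GROUPS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, n, density=0.7):
    """Random nonnegative symmetric weighted adjacency with zero diagonal."""
    W = rng.uniform(0.0, 1.0, size=(n, n))
    keep = rng.random((n, n)) < density
    W = W * keep
    W = np.triu(W, 1)
    return W + W.T


def random_directed(rng, n, density=0.7):
    W = rng.uniform(0.0, 1.0, size=(n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(W, 0.0)
    return W
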