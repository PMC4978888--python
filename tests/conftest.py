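"""Shared fixtures: a small synthetic collection reused across test modules."""

import numpy as np
import pytest

from germpred import SimulationConfig, compute_grm, simulate_collection
from germpred.qc import impute_missing


@pytest.fixture(scope="session")
def small_collection():
    """A desk-scale collection: 300 accessions, 400 markers, 6 trials, 3 states."""
    cfg = SimulationConfig(n_accessions=300, p_markers=400, n_trials=6, seed=7)
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_kinship(small_collection):
    return compute_grm(impute_missing(small_collection.genotypes))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_inbred_panel(rng, n, p, theta_low=0.1, theta_high=0.9):
    """Fully inbred dosages {0, 2} at uniform allele frequencies."""
    from germpred import GenotypeMatrix

    theta = rng.uniform(theta_low, theta_high, p)
    dosages = 2.0 * (rng.random((n, p)) < theta)
    # drop markers fixed in-sample (possible at small n) so the GRM is defined
    freq = dosages.mean(axis=0) / 2.0
    keep = (freq > 0) & (freq < 1)
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)],
        [f"m{j}" for j in np.flatnonzero(keep)],
        dosages[:, keep],
    ).with_theta()
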