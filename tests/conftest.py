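"""Shared fixtures: small synthetic studies and planted low-rank matrices."""

import numpy as np
import pytest

from dbmcov import CohortSpec, default_truth, generate_behavior, generate_cohort, generate_jacobians
from dbmcov.synthetic import brain_mask


def planted_matrix(m, n, k, seed, noise=0.0):
    """Non-negative X = W0 H0 with k disjoint-support components (+ noise)."""
    rng = np.random.default_rng(seed)
    W0 = np.zeros((m, k))
    blk = m // k
    for j in range(k):
        W0[j * blk : (j + 1) * blk, j] = rng.uniform(0.5, 1.5, blk)
    W0 /= np.linalg.norm(W0, axis=0)
    H0 = rng.uniform(0.5, 2.0, (k, n))
    X = W0 @ H0
    if noise:
        X = np.abs(X + noise * rng.standard_normal((m, n)))
    return X, W0, H0


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_per_cell=6, grid_shape=(16, 16, 16), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return default_truth(small_spec, k0=4)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_truth):
    return generate_cohort(small_spec, small_truth)


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return brain_mask(small_spec)


@pytest.fixture(scope="session")
def small_images(small_spec, small_truth, small_cohort):
    return generate_jacobians(small_cohort, small_truth, small_spec, flavor="relative")


@pytest.fixture(scope="session")
def small_behavior(small_spec, small_truth, small_cohort):
    return generate_behavior(small_cohort, small_truth, small_spec)
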