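"""Shared fixtures: a small, fast synthetic study system."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import sparse

from basstrack.preprocess import clean_series
from basstrack.synthetic import (
    SimConfig,
    gen_field,
    gen_tag_series,
    gen_trajectory,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 12x12-cell domain, 60 days: fast enough for unit tests."""
    return SimConfig(
        seed=7,
        lat_bounds=(50.0, 53.0),
        lon_bounds=(0.0, 3.0),
        grid_spacing=0.25,
        n_days=60,
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return gen_field(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_field):
    return gen_trajectory(small_config, small_field, tag_id="tagA")


@pytest.fixture(scope="session")
def small_series(small_config, small_field, small_truth):
    return gen_tag_series(small_truth, small_field, small_config)


@pytest.fixture(scope="session")
def small_clean(small_series, small_field):
    return clean_series(small_series, field=small_field)


def enumerate_posteriors(lik: np.ndarray, K, prior: np.ndarray):
    """Independent oracle: smoothed marginals and the MAP path by summing
    (resp. maximising) over every possible cell sequence."""
    T, n = lik.shape
    Kd = K.toarray() if sparse.issparse(K) else np.asarray(K)
    paths = np.array(list(itertools.product(range(n), repeat=T)))
    with np.errstate(divide="ignore"):
        logp = np.log(prior[paths[:, 0]]) + np.log(lik[0][paths[:, 0]])
        for t in range(1, T):
            logp = logp + np.log(Kd[paths[:, t - 1], paths[:, t]]) + np.log(
                lik[t][paths[:, t]]
            )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    marginals = np.zeros((T, n))
    for t in range(T):
        np.add.at(marginals[t], paths[:, t], w)
    return marginals, paths[np.argmax(logp)]


def random_hmm_instance(rng: np.random.Generator, max_cells=10, max_days=5):
    """A random small HMM instance (likelihoods, kernel, prior)."""
    n = int(rng.integers(2, max_cells + 1))
    T = int(rng.integers(1, max_days + 1))
    lik = rng.random((T, n)) + 1e-3
    K = rng.random((n, n)) + 1e-3
    K /= K.sum(axis=1, keepdims=True)
    prior = rng.random(n) + 1e-3
    prior /= prior.sum()
    return lik, sparse.csr_matrix(K), prior
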