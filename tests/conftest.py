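import numpy as np
import pytest

from gwpred import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_design(rng, n, p, n_causal=None, noise_sd=1.0):
    """Standardized random design with a sparse linear signal.

    Returns (X, y, beta_true) with population-standardized columns and
    centered response; used across solver and evaluation tests.
    """
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.zeros(p)
    k = n_causal if n_causal is not None else max(1, p // 4)
    idx = rng.choice(p, size=k, replace=False)
    beta[idx] = rng.normal(scale=2.0, size=k)
    y = X @ beta + rng.normal(scale=noise_sd, size=n)
    return X, y - y.mean(), beta


def orthonormal_design(rng, n):
    """n x n design with X'X = n*I (so X'X/n = I on the solver scale)."""
    Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    return Q * np.sqrt(n)


#: small but non-trivial simulation shared across simulator tests
SMALL_SIM = SimConfig(
    generation_sizes=(40, 80, 80, 100),
    n_markers=400,
    n_chromosomes=4,
    founder_haplotype_pool=10,
    seed=3,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SMALL_SIM)
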