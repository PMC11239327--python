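import numpy as np
import pytest

from hmmbiclust import ExpressionMatrix, Hyperparams, LatentState, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_params(p, K, rng, constrained=True):
    """Random but valid parameters for testing likelihood/kernel code."""
    omega = rng.dirichlet(np.ones(K))
    xi = np.stack([rng.dirichlet(np.ones(3)) for _ in range(3)])
    mag = 0.5 + rng.random((K, 2))
    mu_cluster = mag * np.array([1.0, -1.0])[None, :] if constrained \
        else rng.normal(size=(K, 2))
    sigma2_cluster = 0.5 + rng.random((K, 2))
    mu_feature = rng.normal(size=(p, K, 2))
    sigma2_feature = 0.5 + rng.random((p, K, 2))
    sigma2_irrelevant = 0.5 + rng.random(p)
    return ModelParams(omega, xi, mu_cluster, sigma2_cluster,
                       mu_feature, sigma2_feature, sigma2_irrelevant)


def make_state(n, p, K, rng):
    return LatentState(z=1 + rng.integers(0, K, size=n),
                       rho=1 + rng.integers(0, 3, size=(p, K)))


@pytest.fixture
def tiny_problem(rng):
    """n=2, p=3, K=1 instance with fixed continuous parameters."""
    n, p, K = 2, 3, 1
    Y = ExpressionMatrix(rng.normal(size=(n, p)))
    params = make_params(p, K, rng)
    hp = Hyperparams(K=K)
    return Y, params, hp
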