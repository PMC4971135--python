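import numpy as np
import pytest

from crydx.gmm_core import GMMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gmm(K: int, D: int, seed: int = 0, spread: float = 3.0) -> GMMParams:
    r = np.random.default_rng(seed)
    return GMMParams(
        weights=r.dirichlet(np.ones(K) * 4.0),
        means=r.standard_normal((K, D)) * spread,
        variances=np.exp(r.uniform(-0.7, 0.7, size=(K, D))),
    )


@pytest.fixture
def gmm_factory():
    return random_gmm
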