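import numpy as np
import pytest

from phidyn import synthetic as syn
from phidyn.io import RegionalMap


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_connectome():
    return syn.synthetic_connectome(20, 0.3, "modular", seed=1)


@pytest.fixture(scope="session")
def coords40():
    return np.random.default_rng(7).uniform(0, 1, size=(40, 3))


@pytest.fixture(scope="session")
def smooth_map(coords40):
    return syn.spatial_map(coords40, corr_length=0.4, seed=3)


@pytest.fixture(scope="session")
def spatial_w(coords40):
    return syn.distance_weights(coords40)


def random_stationary_var(rng, d1, d2, radius=0.9):
    """Random stationary VAR(1) with a full-rank innovation covariance."""
    n = d1 + d2
    a = rng.normal(0, 0.5 / np.sqrt(n), (n, n))
    rho = np.max(np.abs(np.linalg.eigvals(a)))
    if rho > 0:
        a *= radius * rng.uniform(0.3, 1.0) / rho
    ell = rng.normal(0, 1, (n, n))
    q = ell @ ell.T + 0.1 * np.eye(n)
    return a, q
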