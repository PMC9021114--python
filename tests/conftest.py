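import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

import ggmagna as gg
from ggmagna.gaussian_family import CorrelationData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_network(rng):
    """A 5-node true network with its implied correlation matrix."""
    return gg.generate_true_network(5, seed=rng)


@pytest.fixture
def homogeneous_datasets(small_network, rng):
    """Three studies simulated from one network with no heterogeneity."""
    q = 5 * 4 // 2
    return gg.simulate_studies(
        small_network, np.zeros((q, q)), 3, (300, 600), seed=rng
    )


def random_pd_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    """A well-conditioned random correlation matrix."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T + p * np.eye(p)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@pytest.fixture
def pd_corr_4(rng):
    return random_pd_correlation(4, rng)


@pytest.fixture
def corr_data_4(pd_corr_4):
    return CorrelationData(R=pd_corr_4, n=500)
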