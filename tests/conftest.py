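import numpy as np
import pytest

from elanull.datatypes import PmemModel, VarModel
from elanull.simulate import hcp_like_series


@pytest.fixture(scope="session")
def hcp_series():
    """One HCP-like pseudo-real sample (N=7, T=8000) shared across tests."""
    series, model = hcp_like_series(seed=12345, n_channels=7, n_samples=8000)
    return series, model


@pytest.fixture
def ar1_model():
    """Scalar-friendly 2-channel diagonal AR(1) with phi = 0.6."""
    return VarModel(A1=0.6 * np.eye(2), Sigma=np.eye(2), mu=np.zeros(2))


def random_pmem(n_channels: int, scale: float, rng) -> PmemModel:
    h = rng.uniform(-scale, scale, n_channels)
    j = rng.uniform(-scale, scale, (n_channels, n_channels))
    j = 0.5 * (j + j.T)
    np.fill_diagonal(j, 0.0)
    return PmemModel(h, j)
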