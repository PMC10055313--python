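import numpy as np
import pytest

from smash.io import SpatialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """50 genes × 120 spots of null (iid normal, shifted non-negative) data."""
    K, N = 50, 120
    Y = rng.standard_normal((K, N))
    Y -= Y.min(axis=1, keepdims=True)
    return SpatialDataset(
        expression=Y,
        coords=rng.uniform(0, 1, (N, 2)),
        gene_ids=np.array([f"g{i:03d}" for i in range(K)], dtype=object),
        spot_ids=np.array([f"s{i:03d}" for i in range(N)], dtype=object),
    )


def make_dataset(rng, K=10, N=60, d=2, labels=None, covariates=None):
    Y = np.abs(rng.standard_normal((K, N)))
    return SpatialDataset(
        expression=Y,
        coords=rng.uniform(0, 1, (N, d)),
        gene_ids=np.array([f"g{i:03d}" for i in range(K)], dtype=object),
        spot_ids=np.array([f"s{i:03d}" for i in range(N)], dtype=object),
        labels=labels,
        covariates=covariates,
    )
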