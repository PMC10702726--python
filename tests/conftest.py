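import numpy as np
import pytest

from dpelm.datasets import SplitSpec, make_blobs_dataset, split_train_test


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_split():
    """A well-separated two-class blob task split 120/80 — easy for any trainer."""
    ds = make_blobs_dataset(n=8, m=2, N=200, separation=10.0, noise_sd=1.0, seed=7)
    return split_train_test(ds, SplitSpec(n_train=120, stratified=True, seed=7))


@pytest.fixture(scope="session")
def blob_train(blob_split):
    return blob_split[0]


@pytest.fixture(scope="session")
def blob_test(blob_split):
    return blob_split[1]
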