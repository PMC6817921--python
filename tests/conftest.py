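import numpy as np
import pytest

from kboost import SyntheticSpec, TabularDataset, fixture_suite, make_imbalanced


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blobs_ir5():
    """Well-separated two-class blobs, IR 5, used across selection/ensemble tests."""
    return make_imbalanced(SyntheticSpec(n=300, ir=5.0, dims=4, separation=6.0, seed=7))


@pytest.fixture
def twelve_row_ds():
    """12 rows, 3 numeric columns, labels {pos x4, neg x8}."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 3))
    y = np.array([1] * 4 + [0] * 8)
    return TabularDataset(features=X, labels=y, feature_names=["a", "b", "c"])
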