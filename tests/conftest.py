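import numpy as np
import pytest

from veinsemble.ensemble import FeatureData, featurize_samples
from veinsemble.synthetic_data import generate_dataset

#: classifier input used throughout the tests (smallest legal size for the
#: six-pool architecture; keeps CNN cost at desk scale)
TEST_INPUT_SHAPE = (64, 64)


@pytest.fixture(scope="session")
def ds10():
    """Default 10-class, two-session benchmark dataset (in memory)."""
    return generate_dataset(10, 2, 6, master_seed=0)


@pytest.fixture(scope="session")
def ds10_split(ds10):
    return ds10.sspp_split()


@pytest.fixture(scope="session")
def ds10_features(ds10_split):
    """Featurized train/test stacks of the 10-class benchmark."""
    train, test = ds10_split
    tr = featurize_samples(train, input_shape=TEST_INPUT_SHAPE)
    te = featurize_samples(test, input_shape=TEST_INPUT_SHAPE)
    return tr, te


@pytest.fixture(scope="session")
def ds4():
    """Tiny 4-class dataset for fast orchestration tests."""
    return generate_dataset(4, 2, 2, master_seed=3)


@pytest.fixture(scope="session")
def ds4_features(ds4):
    train, test = ds4.sspp_split()
    tr = featurize_samples(train, input_shape=TEST_INPUT_SHAPE)
    te = featurize_samples(test, input_shape=TEST_INPUT_SHAPE)
    return tr, te


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
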