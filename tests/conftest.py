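import numpy as np
import pytest

import ssdfrn as s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schema():
    return s.FeatureSchema()


@pytest.fixture
def synthetic_table():
    """Standardized 58-sample synthetic table with biomass labels."""
    return s.standardize(s.simulate(s.SimConfig(n=58, seed=7)))


@pytest.fixture
def tiny_train_config():
    """Short schedule for tests that only exercise the mechanics."""
    return s.TrainConfig(epochs_stage1=15, epochs_stage2=15, seed=3)
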