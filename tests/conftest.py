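import numpy as np
import pytest

from biomotion import GaitParams, MotionModel, generate_motion
from biomotion.config import RunConfig


@pytest.fixture(scope="session")
def walk_trained_model() -> MotionModel:
    """A model trained for 20 repetitions on the walking-like motion
    (egocentric view), shared across tests that only read its state."""
    model = MotionModel(seed=0)
    seq = generate_motion("gaitA", GaitParams(seed=0), T=360)
    for rep in range(20):
        model.train_sequence(seq)
    return model


@pytest.fixture(scope="session")
def walk_last_record(walk_trained_model):
    """Winner record of one further stimulus-driven interval (no learning)."""
    seq = generate_motion("gaitA", GaitParams(seed=555), T=360)
    return walk_trained_model.test_sequence(seq, label=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig(seed=0)
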