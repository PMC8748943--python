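import numpy as np
import pytest

from cardiomotor import RPeakTrain, SimulationConfig, generate_dyad_dataset, generate_rr_train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_train():
    """Constant 825-ms R-R train, ~100 beats."""
    return generate_rr_train(100, mean_rr=825, sd_rr=0)


@pytest.fixture
def long_train():
    """Variable train long enough to host a few hundred paced events."""
    return generate_rr_train(800, mean_rr=825, sd_rr=40, seed=7)


@pytest.fixture
def small_dataset():
    """Two-dyad dataset under the default (uniform) coupling."""
    return generate_dyad_dataset(SimulationConfig(n_dyads=2), seed=11)
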