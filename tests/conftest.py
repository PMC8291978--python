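import numpy as np
import pytest

from mfgc import synthetic
from mfgc.neuron import SimConfig
from mfgc.stimulus import SpikeTrain


@pytest.fixture(scope="session")
def presets():
    return synthetic.default_presets()


@pytest.fixture(scope="session")
def wt(presets):
    return presets["WT"]


@pytest.fixture(scope="session")
def ko(presets):
    return presets["KO"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_cfg():
    """A 200 ms simulation window at the standard 50 us step."""
    return SimConfig(dt=5e-5, duration=0.2)


def make_train(times, duration=1.0, source_id="t"):
    return SpikeTrain(np.asarray(times, dtype=float), duration, source_id)


@pytest.fixture
def train_factory():
    return make_train
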