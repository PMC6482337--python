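import numpy as np
import pytest

from motregress import SyntheticConfig, TrainConfig, synthesize_subject
from motregress.cnn import train

# a mid-sized subject reused across modules: full-length scan, enough
# non-GM voxels for a meaningful fit, small enough to train in seconds
SMALL = dict(T=135, n_gm=300, n_wm=1500, n_csf=500)


@pytest.fixture(scope="session")
def subject():
    return synthesize_subject(SyntheticConfig(seed=7, **SMALL))


@pytest.fixture(scope="session")
def trained(subject):
    return train(subject.motion, subject.data.non_gm(), TrainConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
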