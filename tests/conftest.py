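import numpy as np
import pytest

from crestvib import OscillatorParams, make_chirp

#: Group-mean resonance parameters of the out-of-plane crest population.
MALE = dict(f_r=26.3, Q=6.2)
FEMALE = dict(f_r=28.1, Q=4.8)


@pytest.fixture(scope="session")
def male_params():
    return OscillatorParams(**MALE)


@pytest.fixture(scope="session")
def female_params():
    return OscillatorParams(**FEMALE)


@pytest.fixture(scope="session")
def study_chirp():
    """The standard sweep protocol: 0-80 Hz at 1.33 Hz/s, 240 Hz sampling."""
    return make_chirp(0.0, 80.0, 1.33, fs=240.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20181128)
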