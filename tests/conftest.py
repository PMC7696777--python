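import numpy as np
import pytest

from eegda import SynthSpec, generate_recording


@pytest.fixture(scope="session")
def alpha_spec():
    """Standard 14-channel alpha-triplet spec used across tests."""
    return SynthSpec(n_channels=14, fs=128.0, duration=60.0,
                     coherent_triplet=(11, 12, 13), band=(8.0, 12.0),
                     coupling=0.8, seed=7)


@pytest.fixture(scope="session")
def alpha_recording(alpha_spec):
    return generate_recording(alpha_spec, "pre")


@pytest.fixture(scope="session")
def small_recording():
    """Short 6-channel recording for cheap preprocessing tests."""
    spec = SynthSpec(n_channels=6, fs=128.0, duration=20.0,
                     coherent_triplet=(0, 1, 2), coupling=0.8, seed=9)
    return generate_recording(spec, "pre")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
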