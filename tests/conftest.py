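import numpy as np
import pytest

from eegsel import SynthConfig, generate_dataset, load_montage


@pytest.fixture(scope="session")
def montage32():
    return load_montage("standard_1020_32")


@pytest.fixture(scope="session")
def montage14():
    return load_montage("emotiv_epoc_14")


@pytest.fixture(scope="session")
def tiny_dataset():
    """One subject, two trials, 12 s at 128 Hz, with blinks and line noise."""
    cfg = SynthConfig(n_subjects=1, n_trials=2, fs_raw=128.0, duration=12.0,
                      seed=42)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
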