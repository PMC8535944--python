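import numpy as np
import pytest

from heartkit import RunConfig
from heartkit.synth import SynthConfig, make_dataset, synth_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def run_cfg():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def clean_recording():
    """A quiet (SNR 30 dB) normal recording at the default 75 bpm."""
    return synth_recording(SynthConfig(duration=8.0, snr_db=30.0, seed=11), "normal")


@pytest.fixture(scope="session")
def small_corpus():
    """15-recording balanced synthetic corpus (5 per class)."""
    manifest, recs = make_dataset(5, seed=7)
    return manifest, recs
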