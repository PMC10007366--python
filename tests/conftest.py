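import numpy as np
import pytest

from pulsewave import signal_core as sc
from pulsewave import synthetic as syn


@pytest.fixture(scope="session")
def default_filter():
    return sc.design_bandpass(50.0)


@pytest.fixture(scope="session")
def clean_waveform():
    """Noise-free, wander-free morphology for exact ground-truth checks."""
    return syn.WaveformParams(noise_sd=0.0, wander_amplitude=0.0,
                              artifact_rate_per_s=0.0)


@pytest.fixture(scope="session")
def clean_signal_60bpm(clean_waveform):
    train = syn.generate_beat_train(60.0, 0.0, 30.0, seed=0)
    sig, truth = syn.render_ppg(train, clean_waveform, fs=50.0, seed=0,
                                duration_s=30.0)
    return sig, truth
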