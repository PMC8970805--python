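"""Shared fixtures: small synthetic trial sets and scalogram batches."""

import numpy as np
import pytest

from mieeg import SynthConfig, generate_mi_eeg
from mieeg.scalogram import TFRConfig, batch_scalograms, stack_pixels


@pytest.fixture(scope="session")
def small_trials():
    """20 trials/class, default ERD and SNR — the workhorse fixture."""
    return generate_mi_eeg(SynthConfig(n_trials_per_class=20, seed=11))


@pytest.fixture(scope="session")
def noisy_trials():
    """0 dB SNR set with its noiseless template (denoising oracle)."""
    return generate_mi_eeg(SynthConfig(n_trials_per_class=30, snr_db=0, seed=3))


@pytest.fixture(scope="session")
def separable_scalograms():
    """Strongly separated scalogram batch (deep ERD, clean signal)."""
    ts = generate_mi_eeg(
        SynthConfig(n_trials_per_class=15, erd_depth=0.9, snr_db=20, seed=1))
    images, labels = batch_scalograms(
        ts, TFRConfig(out_size=(32, 32), n_freqs=32))
    return stack_pixels(images), labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
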