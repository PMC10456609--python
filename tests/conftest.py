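import numpy as np
import pytest

from hrvnet.synthetic_ecg import (ClassProfile, NoiseSpec, generate_rr,
                                  synthesize_ecg)


@pytest.fixture(scope="session")
def clean_train_record():
    """60 beats at exactly 1 Hz, fs=250, zero noise."""
    profile = ClassProfile("NSR", mean_rr=1.0, sd_rr=0.0)
    rr = generate_rr(profile, 59.0, seed=1)
    return synthesize_ecg(rr, 250.0, seed=1)


@pytest.fixture(scope="session")
def noisy_record():
    """Variable-rate record with baseline wander, hum and white noise."""
    profile = ClassProfile("NSR", mean_rr=0.85, sd_rr=0.05, phi=0.3)
    rr = generate_rr(profile, 60.0, seed=11)
    noise = NoiseSpec(baseline_amp=0.2, white_sd=0.05, powerline_amp=0.02)
    return synthesize_ecg(rr, 250.0, noise=noise, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
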