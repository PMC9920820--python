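import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ampt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_sinus():
    """Noise-free 60 bpm sinus record at 200 Hz (60 s)."""
    cfg = ampt.SimConfig(fs=200, duration_s=60, mean_hr_bpm=60,
                         white_sd=0.0, baseline_amp=0.0, seed=2)
    return ampt.generate(cfg)


@pytest.fixture(scope="session")
def clean_sinus_processed(clean_sinus):
    return ampt.preprocess(clean_sinus.record)


@pytest.fixture(scope="session")
def noisy_sinus():
    """~400-beat sinus record at 200 Hz degraded to 20 dB broadband SNR."""
    cfg = ampt.SimConfig(fs=200, duration_s=320, mean_hr_bpm=75,
                         rr_process="gaussian", rr_sd_s=0.03, seed=1)
    return ampt.degrade(ampt.generate(cfg), 20)


@pytest.fixture(scope="session")
def noisy_sinus_processed(noisy_sinus):
    return ampt.preprocess(noisy_sinus.record)


def detection_metrics(result, truth, fs, tolerance_ms=150.0):
    m = ampt.match_beats(result.r_peaks, truth.truth_r_peaks, fs, tolerance_ms)
    return m, ampt.sensitivity(m), ampt.ppv(m)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
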