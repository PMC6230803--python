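import numpy as np
import pytest
from hypothesis import settings

from autosort import (
    DetectionParams,
    PipelineConfig,
    SimConfig,
    bandpass_filter,
    detect_spikes,
    estimate_threshold,
    realign_spikes,
    simulate_recording,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_3units():
    """One cached 3-unit, 60 s, noise-0.1 recording with ground truth."""
    return simulate_recording(SimConfig(n_units=3, noise_sd=0.1,
                                        duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def detected_3units(sim_3units):
    """Detected + realigned spike set of the cached recording."""
    rec, gt = sim_3units
    p = DetectionParams()
    filt = bandpass_filter(rec, p)
    thr = np.array([estimate_threshold(ch) for ch in filt.data])
    spikes = realign_spikes(detect_spikes(filt, p, thr), p)
    return spikes, gt


@pytest.fixture(scope="session")
def blobs_2d():
    """Two well-separated Gaussian blobs in 10 dimensions (SPC fixture)."""
    rng = np.random.default_rng(11)
    a = rng.normal(0.0, 1.0, size=(300, 10))
    b = rng.normal(0.0, 1.0, size=(300, 10))
    b[:, 0] += 10.0
    labels = np.r_[np.zeros(300, dtype=int), np.ones(300, dtype=int)]
    return np.vstack([a, b]), labels
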