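import numpy as np
import pytest

from tremoremg import Recording, SynthParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pd_params():
    """Synthetic regime mimicking an alternating (parkinsonian) tremor."""
    return SynthParams(f_tremor=4.63, delta_phi_deg=154.4, seed=1)


@pytest.fixture
def et_params():
    """Synthetic regime mimicking a synchronous (essential-tremor) tremor."""
    return SynthParams(f_tremor=4.82, delta_phi_deg=38.4, seed=1)


@pytest.fixture
def noise_recording(rng):
    """30 s of white noise posing as an envelope recording (no tremor)."""
    return Recording(rng.standard_normal((2, 6000)), 200.0, stage="envelope")


def sine_recording(freqs_deg, fs=200.0, duration=30.0, stage="envelope"):
    """Two cosine channels: [(f1, phase1_deg), (f2, phase2_deg)]."""
    t = np.arange(int(duration * fs)) / fs
    chans = [np.cos(2 * np.pi * f * t - np.deg2rad(ph)) for f, ph in freqs_deg]
    return Recording(np.stack(chans), fs, stage=stage)
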