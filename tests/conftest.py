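import numpy as np
import pytest

from kpsignal import VoltageRecording
from kpsignal.synthetic import ChannelConfig, SyntheticConfig, generate_recording


@pytest.fixture
def noiseless_three_spike():
    """1 channel, 600 s at 1 Hz, zero noise, 3 spikes of 20 mV at 100/300/500 s."""
    cfg = SyntheticConfig(
        channels=[ChannelConfig(baseline_mean=0.0, noise_std=0.0,
                                spike_times=[100.0, 300.0, 500.0],
                                spike_amplitudes=[20.0, 20.0, 20.0])],
        duration=600.0, fs=1.0, seed=0,
    )
    return generate_recording(cfg)


@pytest.fixture
def two_identical_channels():
    rng = np.random.default_rng(11)
    x = rng.normal(size=500)
    return VoltageRecording(fs=1.0, channels=["ch1", "ch2"],
                           values=np.column_stack([x, x]))
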