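import numpy as np
import pytest

from ibikit import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Five minutes of clean, moderately noisy breathing at 45 bpm."""
    cfg = SimulationConfig(duration=300.0, breath_rate_mean=45.0, seed=11)
    return simulate_recording(cfg)


@pytest.fixture()
def sine_ip():
    """Pure 1 Hz unit-amplitude sinusoid at 62.5 Hz, 120 s."""
    rate = 62.5
    t = np.arange(int(120 * rate)) / rate
    return np.sin(2 * np.pi * t), rate
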