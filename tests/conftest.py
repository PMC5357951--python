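import numpy as np
import pytest

from ecgsonify import sonifier
from ecgsonify.io import ECGRecord


@pytest.fixture(scope="session")
def default_config() -> sonifier.SonificationConfig:
    return sonifier.SonificationConfig()


@pytest.fixture(scope="session")
def zero_control_10s(default_config) -> sonifier.ControlSignal:
    """Constant zero-deviation control at audio rate, 10 s (from a 257 Hz grid)."""
    return sonifier.resample_control(
        np.zeros(2570), 257.0, default_config.audio_sample_rate_hz
    )


@pytest.fixture
def make_record():
    """Factory for small ECGRecords with the six frontal leads."""

    def _make(n_samples=257, n_leads=6, sample_rate_hz=257.0, seed=0):
        rng = np.random.default_rng(seed)
        names = ["I", "II", "III", "aVR", "aVL", "aVF"][:n_leads]
        volts = rng.normal(scale=0.5, size=(n_samples, n_leads))
        return ECGRecord(sample_rate_hz=sample_rate_hz, lead_names=names,
                         voltages=volts)

    return _make
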