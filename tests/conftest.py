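import numpy as np
import pytest

from mepkit.synthetic import Animal, SimConfig, small_config


@pytest.fixture
def animal():
    return Animal("rat_01", "untreated", threshold_mA=1.5, factor=1.0)


@pytest.fixture
def noiseless_cfg():
    """Noise-free, synchronized-carrier configuration: exact closed forms."""
    return SimConfig(
        bg_rms_mV=0.0,
        artifact_rate_hz=0.0,
        carrier_mode="sine",
        n_triggers=20,
        isi_s=0.3,
        pad_s=0.2,
    )


@pytest.fixture
def quick_cfg():
    """Reduced-size noisy configuration for pipeline tests."""
    return small_config()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
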