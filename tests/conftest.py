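import numpy as np
import pytest

from strutkit import OpticalConfig, PrintConditions


@pytest.fixture
def conditions() -> PrintConditions:
    """Reference print conditions: 5 mm/s, ~0.25 mm^3/s (0.25 mg/s of a
    ~1 g/ml ink), water density, no surface tension."""
    return PrintConditions(v_p=5.0, Q=0.25, density=1000.0, gamma=0.0)


@pytest.fixture
def optics_config() -> OpticalConfig:
    """Calibrated stripe-imaging model: 45 deg stripes, 0.5 mm pitch,
    lumped z*dn of 0.15 mm."""
    return OpticalConfig(lumped_zdn=0.15, pattern_angle_deg=45.0, pattern_pitch=0.5)


@pytest.fixture
def spreading_times() -> np.ndarray:
    """Observation times matching the spreading experiments: 24 points
    over 0.5-12 s."""
    return np.linspace(0.5, 12.0, 24)
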