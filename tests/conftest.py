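import numpy as np
import pytest

from calscan import NoiseModel, ScanGeometry, TransientKinetics, WaveModel


@pytest.fixture
def small_geometry() -> ScanGeometry:
    """0.5 mm line at 2 um pitch, 2 ms lines — fast to simulate."""
    return ScanGeometry(n_space=250, pixel_pitch_um=2.0, line_period_ms=2.0)


@pytest.fixture
def kinetics() -> TransientKinetics:
    return TransientKinetics(
        amplitude_dff0=0.8, rise_ms=3.0, tau_decay_ms=50.0, f0_counts=500.0
    )


@pytest.fixture
def no_noise() -> NoiseModel:
    return NoiseModel.none()


@pytest.fixture
def shot_noise() -> NoiseModel:
    return NoiseModel(shot_scale=1.0)


@pytest.fixture
def wave_model() -> WaveModel:
    return WaveModel(
        rate_per_mm_s=6.0,
        velocity_mm_s=2.0,
        amplitude_dff0=0.6,
        extent_um=150.0,
        duration_ms=60.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
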