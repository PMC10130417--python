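import numpy as np
import pytest
from hypothesis import settings

from vpikit import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Reduced 25.6-μm field with default optics; keeps rendering fast."""
    return sd.SimulationConfig(field_size=25.6, seed=0)


@pytest.fixture(scope="session")
def snr10_config():
    """Field whose emitters have peak amplitude ~10x the read noise.

    Peak amplitude = photons / (2π σ_px²) with σ_px = 0.13/0.108 ≈ 1.204 px,
    so 182 photons/frame gives ~20 counts against 2-count read noise per
    frame (10x after 10-frame averaging leaves ample margin).
    """
    return sd.SimulationConfig(field_size=25.6, seed=0, photons_per_fluorophore=182.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
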