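import numpy as np
import pytest

from shapekit.data import ROI
from shapekit.synth import AcquisitionConfig, ResponseModel


@pytest.fixture(scope="session")
def model():
    """Generator truth with the study's programmed sensitivities."""
    return ResponseModel()


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Full-size acquisition with all noise sources off."""
    return AcquisitionConfig(noise_sigma=0.0, floor_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced acquisition (1 frame x 8 lines) for fast unit tests."""
    return AcquisitionConfig(n_frames=1, n_lines=8, noise_sigma=0.0,
                             floor_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def roi():
    return ROI()
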