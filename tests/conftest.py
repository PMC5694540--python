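import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hoverfeed as hf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrations():
    """Noise-free calibration fits at the nominal per-axis slopes."""
    return {
        "horizontal": hf.fit_calibration(hf.generate_calibration_recording(0.159)),
        "vertical": hf.fit_calibration(hf.generate_calibration_recording(0.164)),
    }


@pytest.fixture(scope="session")
def default_trace():
    return hf.generate_strain_trace(hf.StrainSimParams(seed=11))


@pytest.fixture(scope="session")
def symmetric_hover_landmarks():
    """Noise-free, perfectly mirror-symmetric hovering trajectories."""
    return hf.generate_landmark_trajectories(hf.KinematicSimParams(noise_sd_m=0.0, seed=0))


@pytest.fixture(scope="session")
def left_tracking_landmarks():
    return hf.generate_landmark_trajectories(hf.preset_params("left", seed=5))


@pytest.fixture(scope="session")
def left_summary(left_tracking_landmarks):
    return hf.summarize_trial(left_tracking_landmarks)
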