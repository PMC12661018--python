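import numpy as np
import pytest

from thighacc import (
    DeviceModel,
    TriaxialRecording,
    classify_recording,
    downsample,
    simulate_recording,
)
from thighacc.simulator import validation_script


@pytest.fixture(scope="session")
def device25():
    return DeviceModel("sens-plus", dynamic_range_g=4.0, fs_nominal_hz=25.0)


@pytest.fixture(scope="session")
def validation_run():
    """Seven-behaviour validation session at 25 Hz with its 12.5 Hz
    downsampled counterpart and classified labels (shared across tests —
    simulation and classification of 21 min of signal dominate runtime)."""
    rec25, truth = simulate_recording(validation_script(3.0), fs_hz=25.0, seed=1)
    rec12 = downsample(rec25, 12.5)
    return {
        "rec25": rec25,
        "rec12": rec12,
        "truth": truth,
        "labels25": classify_recording(rec25),
        "labels12": classify_recording(rec12),
    }


@pytest.fixture()
def still_pose_recording(device25):
    """Noise-free stills at six well-spread orientations, 30 s each."""
    angles = [(0, 0), (75, 0), (40, 120), (90, 60), (120, 200), (160, 300)]
    chunks = []
    for th, az in angles:
        th, az = np.radians(th), np.radians(az)
        g = np.array([np.cos(th), np.sin(th) * np.sin(az), np.sin(th) * np.cos(az)])
        chunks.append(np.tile(g, (750, 1)))
    return TriaxialRecording(device25, 0.0, 25.0, np.vstack(chunks))
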