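import numpy as np
import pytest

from faststart.kinematics import AnalysisConfig
from faststart.simulate import CStartModelParams, simulate_trajectory
from faststart.trajectory import TrackedTrajectory


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def clean_trial():
    """One noise-free simulated trial with its ground truth."""
    return simulate_trajectory(CStartModelParams(noise_sd_cm=0.0, seed=11))


@pytest.fixture
def noisy_trial():
    """One simulated trial with realistic 0.02 cm tracking noise."""
    return simulate_trajectory(CStartModelParams(noise_sd_cm=0.02, seed=11))


@pytest.fixture
def traj_factory():
    return make_trajectory


def make_trajectory(
    com,
    snout=None,
    frame_rate=240.0,
    stimulus_frame=0,
    stimulus_xy=(50.0, 0.0),
    **kw,
):
    """Hand-built trajectory from a CoM array; snout defaults to CoM+(1,0)."""
    com = np.asarray(com, dtype=float)
    n = len(com)
    if snout is None:
        snout = com + np.array([1.0, 0.0])
    frames = np.arange(n)
    return TrackedTrajectory(
        frames=frames,
        time_s=frames / frame_rate,
        com_xy_cm=com,
        snout_xy_cm=np.asarray(snout, dtype=float),
        frame_rate_hz=frame_rate,
        stimulus_frame=stimulus_frame,
        stimulus_xy_cm=stimulus_xy,
        **kw,
    )
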