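import numpy as np
import pytest

from reachkin.minjerk import min_jerk_profile
from reachkin.simulate import SimConfig, synth_reach_trial


@pytest.fixture(scope="session")
def minjerk_reach():
    """Noiseless straight 3D minimum-jerk reach, A = 30 cm, T = 1 s,
    fs = 120 (capture-rate variant)."""
    t, pos, speed = min_jerk_profile(30.0, 1.0, 120.0)
    direction = np.array([0.6, 0.8, 0.0])
    path = pos[:, None] * direction[None, :]
    return t, path, speed


@pytest.fixture(scope="session")
def impaired_trial():
    """A representative impaired reach: three submovements, curved path,
    trunk compensation, noiseless."""
    cfg = SimConfig(
        n_submovements=3,
        path_curvature_gain=0.1,
        trunk_translation=5.0,
        trunk_rotation=8.0,
        marker_noise_sd=0.0,
        seed=11,
    )
    return synth_reach_trial(cfg, target_index=9)
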