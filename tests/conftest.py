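"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scos import (
    STATIC,
    CameraModel,
    ChannelSet,
    SceneSpec,
    SpeckleParams,
    estimate_beta,
    simulate_scene,
    simulate_speckle_stack,
)

settings.register_profile(
    "scos",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("scos")

#: Sensor model at the instrument operating point: 2 e-/DN, 2 DN read noise, 8-bit.
CAMERA = CameraModel(gain_e_per_dn=2.0, read_noise_dn=2.0, bit_depth=8)

#: Same noise, 12-bit range: used where the closed-form visibility oracle is the
#: reference, whose premise (unclipped intensity statistics) an 8-bit range
#: violates at high contrast — the speckle tail would saturate and bias K^2 low.
CAMERA_DEEP = CameraModel(gain_e_per_dn=2.0, read_noise_dn=2.0, bit_depth=12)

#: Operating point of the simulated instrument: 6 ms exposure at 40 frames/s.
EXPOSURE = 6e-3
FRAME_RATE = 40.0


def small_params(x: float, frame: int = 128, **kw) -> SpeckleParams:
    """Parameters at exposure-to-decorrelation ratio x on a small sensor crop."""
    return SpeckleParams(tau_c=EXPOSURE / x, frame_shape=(frame, frame), **kw)


@pytest.fixture(scope="session")
def beta_static():
    """Contrast ceiling of the static configuration at full 256x256 scale."""
    params = SpeckleParams(tau_c=STATIC)
    return estimate_beta(params, n_frames=64, seed=101)


@pytest.fixture(scope="session")
def ideal_stacks():
    """Noise-free 64-frame, 256x256 recordings at x = T/tau_c in {0.5, 2, 10}."""
    stacks = {}
    for i, x in enumerate((0.5, 2.0, 10.0)):
        params = SpeckleParams(tau_c=EXPOSURE / x)
        stacks[x] = simulate_speckle_stack(params, None, None, 64, seed=300 + i)
    return stacks


def _scene_channelset(altered, seed):
    params = SpeckleParams(tau_c=3e-3, frame_shape=(64, 64))
    scene = SceneSpec(n_channels=6, n_frames=480, altered_channels=altered, seed=seed)
    rec = simulate_scene(scene, params, CAMERA)
    cset = ChannelSet.from_stacks(rec.stacks, baseline_window=(0.0, 5.0))
    return rec, cset


@pytest.fixture(scope="session")
def healthy_scene():
    """Six channels sharing one cardiac waveform (12 s at 40 FPS, 64x64 crops)."""
    return _scene_channelset(altered=(), seed=11)


@pytest.fixture(scope="session")
def injured_scene():
    """Channels 1-2 driven by an independent altered waveform (injury emulation)."""
    return _scene_channelset(altered=(0, 1), seed=12)
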