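"""Simulator: visibility oracle, cardiac waveform, field statistics, scenes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scos
from scos import (
    STATIC,
    CameraModel,
    PulseShape,
    SceneSpec,
    SpeckleParams,
    compute_raw_contrast,
    constant_waveform,
    estimate_beta,
    generate_cardiac_waveform,
    simulate_scene,
    simulate_speckle_stack,
    theoretical_contrast,
)
from scos.exceptions import SaturationError

from conftest import CAMERA, EXPOSURE, FRAME_RATE, small_params


# ---------------------------------------------------------------------------
# Closed-form visibility curve
# ---------------------------------------------------------------------------

class TestTheoreticalContrast:
    def test_known_values(self):
        assert theoretical_contrast(0.0) == pytest.approx(1.0)
        assert theoretical_contrast(0.0, beta=0.3) == pytest.approx(0.3)
        assert theoretical_contrast(1.0) == pytest.approx((math.exp(-2) + 1) / 2)
        # deep-blur asymptote K^2 -> 1/x
        assert theoretical_contrast(100.0) == pytest.approx(0.01, rel=0.01)
        assert theoretical_contrast(np.inf) == 0.0

    def test_series_matches_direct_formula_at_crossover(self):
        x = 1e-4
        direct = (math.expm1(-2 * x) + 2 * x) / (2 * x**2)
        assert theoretical_contrast(x) == pytest.approx(direct, rel=1e-10)

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            theoretical_contrast(-0.1)

    @given(st.floats(min_value=1e-3, max_value=100.0), st.floats(min_value=1e-3, max_value=50.0))
    def test_strictly_decreasing_and_bounded(self, x1, dx):
        k1 = theoretical_contrast(x1)
        k2 = theoretical_contrast(x1 + dx)
        assert 0 < k2 < k1 <= 1.0


# ---------------------------------------------------------------------------
# Cardiac waveform
# ---------------------------------------------------------------------------

class TestCardiacWaveform:
    def test_sampling_and_fundamental_frequency(self):
        wf = generate_cardiac_waveform(60.0, 5.0, 40.0)
        assert len(wf.sample_times) == 200
        spec = np.abs(np.fft.rfft(wf.relative_flow - wf.relative_flow.mean()))
        freqs = np.fft.rfftfreq(200, 1 / 40.0)
        assert freqs[np.argmax(spec)] == pytest.approx(1.0)

    def test_unit_mean_over_whole_beats(self):
        wf = generate_cardiac_waveform(60.0, 10.0, 40.0)
        assert abs(wf.relative_flow.mean() - 1.0) < 1e-6

    def test_strictly_positive_everywhere(self):
        for hr in (45.0, 60.0, 110.0, 180.0):
            wf = generate_cardiac_waveform(hr, 8.0, 40.0)
            assert np.all(wf.relative_flow > 0)

    def test_deterministic_for_fixed_seed(self):
        shape = PulseShape(variability=0.05)
        a = generate_cardiac_waveform(60.0, 5.0, 40.0, shape_params=shape, seed=7)
        b = generate_cardiac_waveform(60.0, 5.0, 40.0, shape_params=shape, seed=7)
        np.testing.assert_array_equal(a.relative_flow, b.relative_flow)

    def test_systolic_peak_and_dicrotic_notch_per_beat(self):
        from scipy.signal import find_peaks

        # one beat sampled densely: exactly two local maxima, systolic dominant
        wf = generate_cardiac_waveform(60.0, 1.0, 400.0)
        peaks, props = find_peaks(wf.relative_flow, prominence=0.01)
        assert len(peaks) == 2
        assert wf.relative_flow[peaks[0]] > wf.relative_flow[peaks[1]]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heart_rate": 60.0, "duration": -1.0, "frame_rate": 40.0},
            {"heart_rate": 60.0, "duration": 5.0, "frame_rate": 0.0},
            {"heart_rate": 20.0, "duration": 5.0, "frame_rate": 40.0},
            {"heart_rate": 250.0, "duration": 5.0, "frame_rate": 40.0},
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_cardiac_waveform(**kwargs)


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"tau_c": -1e-3},
            {"exposure_T": 0.0},
            {"sp_ratio": 0.0},
            {"sp_ratio": 2.5},
            {"beta": 1.5},
            {"exposure_T": 30e-3, "frame_rate": 40.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SpeckleParams(**kw)

    def test_static_sentinel(self):
        assert SpeckleParams(tau_c=STATIC).static
        assert not SpeckleParams(tau_c=1e-3).static

    def test_camera_saturation_level(self):
        assert CameraModel(gain_e_per_dn=2.0, bit_depth=8).max_dn == 255
        assert CameraModel(gain_e_per_dn=2.0, bit_depth=12).max_dn == 4095


# ---------------------------------------------------------------------------
# Simulated stacks
# ---------------------------------------------------------------------------

class TestSimulatedStacks:
    def test_identical_seed_gives_bit_identical_stacks(self):
        params = small_params(2.0, frame=32)
        wf = constant_waveform(1.0, FRAME_RATE)
        a = simulate_speckle_stack(params, CAMERA, wf, 8, seed=5)
        b = simulate_speckle_stack(params, CAMERA, wf, 8, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = simulate_speckle_stack(params, CAMERA, wf, 8, seed=6)
        assert not np.array_equal(a.frames, c.frames)

    def test_mean_intensity_control(self):
        # noise-free mean within 2% of mean_level
        params = small_params(1.0, mean_level=100.0)
        stack = simulate_speckle_stack(params, None, None, 16, seed=9)
        assert stack.frames.mean() == pytest.approx(100.0, rel=0.02)

    def test_static_contrast_equals_measured_ceiling(self):
        params = SpeckleParams(tau_c=STATIC, frame_shape=(128, 128))
        est = estimate_beta(params, n_frames=32, seed=21)
        stack = simulate_speckle_stack(params, None, None, 4, seed=22)
        k2 = compute_raw_contrast(stack.frames[0])
        assert k2 == pytest.approx(est.beta_hat, rel=0.02)
        # frozen field: every frame identical
        np.testing.assert_array_equal(stack.frames[0], stack.frames[-1])

    def test_fast_dynamics_washes_out_contrast(self):
        params = small_params(50.0)
        est = estimate_beta(SpeckleParams(tau_c=STATIC, frame_shape=(128, 128)), 16, seed=23)
        stack = simulate_speckle_stack(params, None, None, 4, seed=24)
        k2 = np.mean([compute_raw_contrast(f) for f in stack.frames])
        assert k2 < 0.05 * est.beta_hat

    def test_contrast_strictly_decreasing_in_x(self):
        means = []
        for i, x in enumerate((0.1, 0.3, 1.0, 3.0, 10.0)):
            stack = simulate_speckle_stack(small_params(x), None, None, 8, seed=30 + i)
            means.append(np.mean([compute_raw_contrast(f) for f in stack.frames]))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_contrast_tracks_visibility_curve_at_reduced_scale(self):
        est = estimate_beta(SpeckleParams(tau_c=STATIC, frame_shape=(128, 128)), 32, seed=40)
        for i, x in enumerate((0.1, 1.0)):
            stack = simulate_speckle_stack(small_params(x), None, None, 32, seed=41 + i)
            k2 = np.mean([compute_raw_contrast(f) for f in stack.frames])
            assert k2 == pytest.approx(theoretical_contrast(x, est.beta_hat), rel=0.015)

    def test_saturating_mean_level_rejected(self):
        params = small_params(1.0, frame=32, mean_level=300.0)
        with pytest.raises(SaturationError):
            simulate_speckle_stack(params, CAMERA, None, 2, seed=1)

    def test_waveform_must_cover_recording(self):
        wf = constant_waveform(0.1, FRAME_RATE)
        with pytest.raises(ValueError):
            simulate_speckle_stack(small_params(1.0, frame=32), None, wf, 40, seed=1)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

class TestScenes:
    def test_transmission_scales_mean_intensity_linearly(self):
        params = small_params(2.0, frame=32)
        scene = SceneSpec(n_channels=2, n_frames=80, transmission=(1.0, 0.5), seed=3)
        rec = simulate_scene(scene, params, CAMERA)
        m1 = rec.stacks["ch1"].frames.mean()
        m2 = rec.stacks["ch2"].frames.mean()
        assert m2 / m1 == pytest.approx(0.5, abs=0.02)

    def test_scene_validation(self):
        with pytest.raises(ValueError):
            SceneSpec(n_channels=3, transmission=(1.0, 1.0))  # length mismatch
        with pytest.raises(ValueError):
            SceneSpec(n_channels=2, altered_channels=(5,))
        with pytest.raises(ValueError):
            SceneSpec(n_channels=0)

    def test_shared_waveform_channels_correlate(self, healthy_scene):
        # full pipeline on the simulated healthy scene: all pairs strongly coupled
        from scos import correlation_matrix

        _, cset = healthy_scene
        result = correlation_matrix(cset)
        assert result.pairs["rho"].min() > 0.75

    def test_altered_channels_decouple(self, injured_scene):
        from scos import correlation_matrix

        _, cset = injured_scene
        result = correlation_matrix(cset)
        assert result.rho("ch1", "ch2") > 0.75
        for j in ("ch3", "ch4", "ch5", "ch6"):
            assert result.rho("ch1", j) < 0.5
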