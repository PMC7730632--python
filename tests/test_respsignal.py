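"""ROI-mean signal, smoothing, breath segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthresp.errors import SignalError
from depthresp.io_formats import DepthSequence
from depthresp.respsignal import RespSignal, detect_breaths, roi_mean_signal, smooth
from depthresp.roi import ROIRect


def _signal(x, rate=30.0):
    x = np.asarray(x, float)
    return RespSignal(np.arange(x.size) / rate, x, rate)


class TestRoiMeanSignal:
    def test_static_scene_is_zero(self):
        seq = DepthSequence(np.full((10, 30, 30), 1500, np.uint16),
                            np.arange(10) / 30.0)
        sig = roi_mean_signal(seq, ROIRect(0, 30, 0, 30))
        assert np.allclose(sig.x, 0.0)

    def test_approach_raises_signal(self):
        # torso moves 5 mm toward the camera: depth falls, x rises by 5
        frames = np.full((10, 20, 20), 1500, np.uint16)
        frames[5:] = 1495
        seq = DepthSequence(frames, np.arange(10) / 30.0)
        sig = roi_mean_signal(seq, ROIRect(0, 20, 0, 20))
        assert sig.x.max() - sig.x.min() == pytest.approx(5.0, abs=1e-9)
        assert sig.x[-1] > sig.x[0]

    def test_partial_roi_coverage_scales_amplitude(self, noiseless_recording):
        # ROI covering the chest plus static margin: signal amplitude is
        # the piston displacement scaled by the moving-area fraction,
        # verified against a brute-force mean over the rendered frames
        seq, truth = noiseless_recording
        scene = truth.scene
        r0, r1 = scene.chest_row_span
        roi = ROIRect(r0, r1, scene.center_col - 30, scene.center_col + 30)
        sig = roi_mean_signal(seq, roi, 30.0)
        patch = seq.frames[:, roi.top:roi.bottom, roi.left:roi.right]
        brute = -patch.mean(axis=(1, 2))
        brute -= brute.mean()
        # resampling at the native frame rate: identical grids
        np.testing.assert_allclose(sig.x[:brute.size], brute, atol=1e-6)

    def test_fully_invalid_frame_reports_index(self):
        frames = np.full((5, 20, 20), 1500, np.uint16)
        frames[3] = 0
        seq = DepthSequence(frames, np.arange(5) / 30.0)
        with pytest.raises(SignalError, match="frame 3"):
            roi_mean_signal(seq, ROIRect(0, 20, 0, 20))


class TestSmooth:
    def test_constant_unchanged(self):
        sig = _signal(np.full(100, 2.5))
        assert np.allclose(smooth(sig, 0.5).x, 2.5)

    def test_impulse_flat_top(self):
        x = np.zeros(99)
        x[50] = 1.0
        out = smooth(_signal(x), 0.5).x  # window = 15 samples
        assert np.allclose(out[43:58], 1 / 15)
        assert np.allclose(out[:43], 0) and np.allclose(out[58:], 0)

    def test_sinusoid_attenuation_matches_dirichlet_kernel(self):
        # closed-form gain of an N-point moving average at frequency f
        f, rate, n_win = 0.2, 30.0, 15
        t = np.arange(3000) / rate
        sig = _signal(np.sin(2 * np.pi * f * t))
        out = smooth(sig, n_win / rate).x
        gain_expected = abs(
            np.sin(np.pi * f * n_win / rate)
            / (n_win * np.sin(np.pi * f / rate))
        )
        mid = slice(500, 2500)  # avoid edges
        gain = out[mid].std() / sig.x[mid].std()
        assert gain == pytest.approx(gain_expected, rel=1e-3)

    def test_zero_phase_peak_not_shifted(self):
        t = np.arange(600) / 30.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = smooth(_signal(x), 0.5).x
        assert abs(int(np.argmax(out[:300])) - int(np.argmax(x[:300]))) <= 1


class TestDetectBreaths:
    def test_sinusoid_anatomy(self):
        # 3 mm, 0.2 Hz, 60 s: ~12 breaths, amplitude 6 mm, interval 5 s
        rate = 30.0
        t = np.arange(int(60 * rate)) / rate
        x = 3.0 * np.sin(2 * np.pi * 0.2 * t)
        ev = detect_breaths(_signal(x))
        assert abs(ev.peaks.size - 12) <= 1
        np.testing.assert_allclose(ev.amplitudes, 6.0, rtol=0.01)
        np.testing.assert_allclose(ev.intervals, 5.0, atol=1 / rate)

    def test_monotone_ramp_is_signal_error(self):
        with pytest.raises(SignalError):
            detect_breaths(_signal(np.linspace(0, 10, 300)))

    def test_jitter_does_not_change_peak_count(self):
        rate = 30.0
        t = np.arange(int(60 * rate)) / rate
        clean = 3.0 * np.sin(2 * np.pi * 0.25 * t)
        noisy = clean + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        clean_ev = detect_breaths(smooth(_signal(clean), 0.5))
        noisy_ev = detect_breaths(smooth(_signal(noisy), 0.5))
        assert noisy_ev.peaks.size == clean_ev.peaks.size

    def test_alternation_and_positive_amplitudes(self, rng):
        t = np.arange(1800) / 30.0
        x = 2.0 * np.sin(2 * np.pi * 0.2 * t) + 0.2 * rng.normal(size=t.size)
        ev = detect_breaths(smooth(_signal(x), 0.5))
        merged = np.empty(2 * ev.peaks.size, int)
        merged[0::2], merged[1::2] = ev.valleys, ev.peaks
        assert np.all(np.diff(merged) > 0)
        assert np.all(ev.amplitudes > 0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        scale=st.floats(0.5, 20.0),
        shift_samples=st.integers(0, 90),
    )
    def test_scale_and_shift_equivariance(self, scale, shift_samples):
        rate = 30.0
        t = np.arange(int(45 * rate)) / rate
        base = 3.0 * np.sin(2 * np.pi * 0.25 * t) + 0.5 * np.sin(
            2 * np.pi * 0.5 * t)
        ev = detect_breaths(_signal(base))
        # amplitude scaling: amplitudes scale, intervals unchanged
        ev_s = detect_breaths(_signal(base * scale))
        np.testing.assert_allclose(ev_s.amplitudes, ev.amplitudes * scale,
                                   rtol=1e-9)
        np.testing.assert_allclose(ev_s.intervals, ev.intervals, atol=1e-12)
        # time shift: interior events move by the shift
        shifted = np.roll(base, shift_samples)
        ev_t = detect_breaths(_signal(shifted))
        interior = (ev.peaks > shift_samples) & (
            ev.peaks < base.size - shift_samples)
        expected = ev.peaks[interior] + shift_samples
        assert set(expected).issubset(set(ev_t.peaks))
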