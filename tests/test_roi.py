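"""Tentative ROI geometry, unit grid, row waveforms, final-ROI cutoff."""

import numpy as np
import pytest

from depthresp.body_landmarks import ShoulderPair
from depthresp.errors import GeometryError, SignalError
from depthresp.io_formats import DepthSequence
from depthresp.roi import (
    ROIRect,
    UnitWaveforms,
    build_tentative_roi,
    build_unit_grid,
    compute_row_waveforms,
    extract_unit_waveforms,
    finalize_roi,
)


class TestTentativeROI:
    def test_direct_construction(self):
        sh = ShoulderPair((100, 150), (110, 350))
        roi = build_tentative_roi(sh, 424, 512, arm_width_px=30)
        assert (roi.top, roi.left, roi.right, roi.bottom) == (110, 180, 320, 424)
        assert roi.stage == "tentative"

    def test_zero_arm_width_uses_shoulder_columns(self):
        sh = ShoulderPair((100, 150), (110, 350))
        roi = build_tentative_roi(sh, 424, 512, arm_width_px=0)
        assert (roi.left, roi.right) == (150, 350)

    def test_excessive_arm_width_is_geometry_error(self):
        sh = ShoulderPair((100, 150), (110, 350))
        with pytest.raises(GeometryError):
            build_tentative_roi(sh, 424, 512, arm_width_px=120)


class TestUnitGrid:
    def test_grid_count_matches_enumeration(self):
        roi = ROIRect(0, 100, 0, 100)
        grid = build_unit_grid(roi, 19, 10)
        # brute-force enumeration of fully contained anchors
        n = len([k for k in range(100) if k * 10 + 19 <= 100])
        assert grid.n_rows == grid.n_cols == n == 9

    def test_exact_unit_roi_is_single_unit(self):
        grid = build_unit_grid(ROIRect(5, 24, 7, 26), 19, 10)
        assert grid.n_rows == grid.n_cols == 1
        assert grid.unit_bounds(0, 0) == (5, 24, 7, 26)

    def test_undersized_roi_is_geometry_error(self):
        with pytest.raises(GeometryError):
            build_unit_grid(ROIRect(0, 18, 0, 50), 19, 10)


def _sequence_from_stack(stack):
    n = stack.shape[0]
    return DepthSequence(stack.astype(np.uint16), np.arange(n) / 30.0)


class TestExtractUnitWaveforms:
    def test_constant_scene_gives_constant_waveforms(self):
        seq = _sequence_from_stack(np.full((5, 40, 40), 1234))
        grid = build_unit_grid(ROIRect(0, 40, 0, 40), 19, 10)
        units = extract_unit_waveforms(seq, grid, 30.0)
        assert np.allclose(units.values, 1234.0)
        assert units.validity.all()

    def test_half_background_unit_averages(self):
        stack = np.full((3, 19, 19), 1000)
        stack[:, :, 9:] = 3000  # ~half torso at 1000, half background 3000
        seq = _sequence_from_stack(stack)
        grid = build_unit_grid(ROIRect(0, 19, 0, 19), 19, 10)
        units = extract_unit_waveforms(seq, grid, 30.0)
        expected = (1000 * 9 * 19 + 3000 * 10 * 19) / (19 * 19)
        assert np.allclose(units.values, expected)

    def test_all_zero_unit_flagged_invalid(self):
        stack = np.full((4, 19, 40), 1000)
        stack[:, :, 21:40] = 0  # second unit column fully dropped out
        seq = _sequence_from_stack(stack)
        grid = build_unit_grid(ROIRect(0, 19, 0, 40), 19, 10)
        units = extract_unit_waveforms(seq, grid, 30.0)
        assert units.validity[0, 0]
        assert not units.validity[0, 2]

    def test_all_invalid_is_signal_error(self):
        seq = _sequence_from_stack(np.zeros((3, 20, 20)))
        grid = build_unit_grid(ROIRect(0, 20, 0, 20), 19, 10)
        with pytest.raises(SignalError):
            extract_unit_waveforms(seq, grid, 30.0)


def _unit_waveforms(row_series, sample_rate=30.0):
    """UnitWaveforms with one unit per row carrying the given series."""
    values = np.asarray(row_series, float)[:, None, :]
    validity = np.ones((values.shape[0], 1), bool)
    t = np.arange(values.shape[2]) / sample_rate
    return UnitWaveforms(values, validity, sample_rate, t)


class TestRowWaveforms:
    def test_amplitude_ratio_four_to_one(self):
        t = np.arange(90) / 30.0
        rows = [2.0 * np.sin(2 * np.pi * t), 0.5 * np.sin(2 * np.pi * t)]
        units = _unit_waveforms(rows)
        out = compute_row_waveforms(units, [(0, 90)])
        np.testing.assert_allclose(out.amplitude_ratio, [0.8, 0.2])

    def test_identical_rows_uniform_ratio(self):
        t = np.arange(60) / 30.0
        rows = [np.sin(2 * np.pi * t)] * 5
        out = compute_row_waveforms(_unit_waveforms(rows), [(0, 60)])
        np.testing.assert_allclose(out.amplitude_ratio, 0.2)

    def test_ratio_sums_to_one_and_cumulative_monotone(self, rng):
        rows = rng.normal(size=(7, 120)).cumsum(axis=1)  # random walks
        out = compute_row_waveforms(_unit_waveforms(rows), [(0, 60), (60, 120)])
        assert out.amplitude_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(out.cumulative_ratio) >= -1e-12)
        assert out.cumulative_ratio[-1] == pytest.approx(1.0, abs=1e-9)

    def test_empty_windows_is_signal_error(self):
        units = _unit_waveforms([np.arange(10.0)])
        with pytest.raises(SignalError):
            compute_row_waveforms(units, [])

    def test_chest_rows_outrank_abdomen_rows(self, noiseless_recording):
        # stronger chest motion must put chest rows ahead in the ratio
        seq, truth = noiseless_recording
        from depthresp.config import RunConfig
        from depthresp.pipeline import run_estimate

        res = run_estimate(seq, RunConfig())
        scene = truth.scene
        chest_rows = [
            r for r in range(res.rows.row_amplitude.size)
            if scene.chest_row_span[0]
            <= res.grid.unit_bounds(r, 0)[0]
            < scene.chest_row_span[1] - res.grid.unit_size
        ]
        below_rows = [
            r for r in range(res.rows.row_amplitude.size)
            if res.grid.unit_bounds(r, 0)[0] >= scene.abdomen_row_span[1]
        ]
        assert chest_rows and below_rows
        assert (res.rows.row_amplitude[chest_rows].min()
                > res.rows.row_amplitude[below_rows].max())


class TestFinalizeROI:
    def _rowset(self, amps):
        from depthresp.roi import RowWaveformSet

        amps = np.asarray(amps, float)
        ratio = amps / amps.sum()
        return RowWaveformSet(
            row_signals=np.zeros((amps.size, 2)),
            row_amplitude=amps,
            amplitude_ratio=ratio,
            cumulative_ratio=np.cumsum(ratio),
            row_valid=np.ones(amps.size, bool),
        )

    def _grid(self, n_rows):
        roi = ROIRect(0, 19 + 10 * (n_rows - 1) + 1, 0, 30)
        return build_unit_grid(roi, 19, 10)

    def test_hand_profile_4321(self):
        grid = self._grid(4)
        final = finalize_roi(grid.roi, self._rowset([4, 3, 2, 1]), grid, 0.90)
        # cumulative [0.4, 0.7, 0.9, 1.0] -> first crossing at row 2
        assert final.bottom == grid.row_bottom_edge(2) == 39

    def test_single_row(self):
        grid = self._grid(1)
        final = finalize_roi(grid.roi, self._rowset([5.0]), grid, 0.90)
        assert final.bottom == grid.row_bottom_edge(0)

    def test_ten_equal_rows_cross_at_ninth(self):
        grid = self._grid(10)
        final = finalize_roi(grid.roi, self._rowset([1.0] * 10), grid, 0.90)
        assert final.bottom == grid.row_bottom_edge(8)

    def test_scale_invariance(self, rng):
        amps = rng.uniform(0.5, 5.0, size=8)
        grid = self._grid(8)
        a = finalize_roi(grid.roi, self._rowset(amps), grid, 0.90)
        b = finalize_roi(grid.roi, self._rowset(amps * 37.5), grid, 0.90)
        assert a == b

    def test_final_within_tentative_same_sides(self, rng):
        amps = rng.uniform(0.1, 3.0, size=6)
        grid = self._grid(6)
        final = finalize_roi(grid.roi, self._rowset(amps), grid, 0.90)
        assert final.stage == "final"
        assert final.top == grid.roi.top
        assert final.left == grid.roi.left
        assert final.right == grid.roi.right
        assert final.bottom <= grid.roi.bottom
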