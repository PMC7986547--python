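import warnings

import numpy as np
import pytest

from telodens import (
    LadderSpec,
    PeakAssignment,
    assign_ladder,
    build_virtual_markers,
    detect_peaks,
    fit_calibration,
    load_ladder_presets,
    predict_length,
)
from telodens.calibration import NonMonotoneLadderWarning

LADDER5 = LadderSpec("L5", (8000, 6000, 4000, 2000, 1000))


def gaussian_bands(n_rows, centers, sigma=2.0, amp=1.0):
    rows = np.arange(n_rows, dtype=float)
    return sum(amp * np.exp(-((rows - c) ** 2) / (2 * sigma**2)) for c in centers)


class TestDetectPeaks:
    def test_single_triangular_peak(self):
        prof = np.concatenate([np.linspace(0, 1, 101), np.linspace(1, 0, 101)[1:]])
        assert detect_peaks(prof, 0.5) == [100]

    def test_equal_gaussian_bands_found_at_centers(self):
        centers = np.linspace(40, 460, 8)
        prof = gaussian_bands(500, centers, sigma=3.0)
        found = detect_peaks(prof, 0.1)
        assert len(found) == 8
        assert np.max(np.abs(np.asarray(found) - centers)) <= 1

    def test_sensitivity_one_keeps_at_most_one_peak(self):
        prof = gaussian_bands(300, [80, 200], sigma=4.0) + gaussian_bands(300, [140], 4.0, 0.4)
        assert len(detect_peaks(prof, 1.0)) <= 1

    def test_invalid_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.ones(10), 0.0)


class TestAssignLadder:
    def test_identity_mapping(self):
        peaks = [50, 100, 150, 200, 250]
        a = assign_ladder(peaks, LADDER5)
        assert a.pairs == [(8000, 50), (6000, 100), (4000, 150), (2000, 200), (1000, 250)]

    def test_partial_mapping_skips_undetected_band(self):
        a = assign_ladder([50, 150, 200, 250], LADDER5, [(0, 0), (2, 1), (3, 2), (4, 3)])
        assert len(a.pairs) == 4 and (6000, 100) not in a.pairs

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError, match="cannot be fitted"):
            assign_ladder([50, 100], LADDER5, [(0, 0), (1, 1)])

    def test_duplicate_peak_index_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_ladder([50, 100, 150], LADDER5, [(0, 0), (1, 0), (2, 2)])

    def test_non_monotone_assignment_warns_not_raises(self):
        with pytest.warns(NonMonotoneLadderWarning):
            assign_ladder([100, 50, 150], LADDER5, [(0, 0), (1, 1), (2, 2)])


class TestFitCalibration:
    def test_exact_line_selects_order_one_with_zero_residuals(self):
        rows = np.array([50.0, 100.0, 150.0, 200.0, 250.0, 300.0])
        bp = 9000.0 - 25.0 * rows
        model = fit_calibration(PeakAssignment(list(zip(bp, rows))))
        assert model.order == 1
        np.testing.assert_allclose(model(rows), bp, rtol=1e-9)

    def test_exact_cubic_recovered_to_numerical_precision(self):
        rows = np.linspace(40, 380, 8)
        coef = [12000.0, -55.0, 0.08, -8e-5]  # ascending powers
        bp = np.polynomial.polynomial.polyval(rows, coef)
        model = fit_calibration(PeakAssignment(list(zip(bp, rows))))
        assert model.order == 3
        np.testing.assert_allclose(model.coefficients, coef, rtol=1e-7)

    def test_noisy_quadratic_selects_order_two_in_most_replicates(self):
        rows = np.linspace(40, 400, 10)
        true = 14000.0 - 60.0 * rows + 0.07 * rows**2
        hits = 0
        n_rep = 50
        sigma = 0.005 * true.mean()  # noise scale: 0.5% of band size
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            bp = true + rng.normal(0, sigma, rows.size)
            model = fit_calibration(PeakAssignment(list(zip(bp, rows))))
            hits += model.order == 2
        assert hits >= 0.9 * n_rep

    def test_alpha_one_reaches_max_order_and_tiny_alpha_stays_linear(self, rng):
        rows = np.linspace(10, 300, 12)
        bp = 9000 - 24 * rows + rng.normal(0, 150, rows.size)
        pairs = PeakAssignment(list(zip(bp, rows)))
        assert fit_calibration(pairs, alpha=1.0, max_order=5).order == 5
        assert fit_calibration(pairs, alpha=1e-12).order == 1

    def test_selected_order_capped_at_pairs_minus_two(self, rng):
        rows = np.linspace(10, 100, 5)
        bp = np.exp((820 - rows) / 85)
        model = fit_calibration(PeakAssignment(list(zip(bp, rows))), alpha=1.0)
        assert model.order <= 3

    def test_duplicated_pairs_leave_coefficients_unchanged(self, rng):
        rows = np.linspace(10, 300, 8)
        bp = 10000 - 30 * rows + 0.02 * rows**2 + rng.normal(0, 20, rows.size)
        pairs = list(zip(bp, rows))
        m1 = fit_calibration(PeakAssignment(pairs), force_order=2)
        m2 = fit_calibration(PeakAssignment(pairs + pairs), force_order=2)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-9)

    def test_repeated_rows_are_a_degenerate_design(self):
        with pytest.raises(ValueError, match="repeated"):
            fit_calibration(PeakAssignment([(8000, 50), (6000, 50), (4000, 100)]))


class TestPredictLength:
    def test_interpolates_exactly_at_support_points(self):
        rows = np.linspace(50, 350, 7)
        bp = 9000 - 24 * rows
        model = fit_calibration(PeakAssignment(list(zip(bp, rows))))
        assert predict_length(model, rows[3]) == pytest.approx(bp[3], rel=1e-9)

    def test_monotone_decreasing_over_fitted_range(self, demo):
        marker = demo["markers"][0]
        peaks = detect_peaks(marker, 0.1)
        ladder = demo["recipe"].ladders[0].ladder
        model = fit_calibration(assign_ladder(peaks, ladder))
        grid = np.linspace(model.fit_rows[0], model.fit_rows[1], 200)
        assert np.all(np.diff(model.predict_length(grid)) < 0)

    def test_far_extrapolation_floors_at_one_bp_with_warning(self):
        rows = np.linspace(50, 350, 7)
        bp = 9000 - 24 * rows
        model = fit_calibration(PeakAssignment(list(zip(bp, rows))))
        with pytest.warns(UserWarning, match="floored"):
            assert predict_length(model, 10000.0) == 1.0


class TestVirtualMarkers:
    @staticmethod
    def _assignment(shift_rows, col, bp=None):
        bp = bp if bp is not None else np.array([8000.0, 6000, 4000, 3000, 2000, 1000])
        rows = 820 - 85 * np.log(bp) + shift_rows
        return PeakAssignment(list(zip(bp, rows)), lane_center_col=col)

    def test_identical_markers_give_identical_lane_models(self):
        left = self._assignment(0.0, 10.0)
        right = self._assignment(0.0, 200.0)
        models = build_virtual_markers(left, right, [50.0, 120.0, 180.0])
        base = fit_calibration(left)
        grid = np.linspace(100, 400, 50)
        for m in models:
            np.testing.assert_allclose(m(grid), base(grid), rtol=1e-9)

    def test_midway_lane_gets_half_the_shift(self):
        left = self._assignment(0.0, 0.0)
        right = self._assignment(10.0, 100.0)
        (model,) = build_virtual_markers(left, right, [50.0])
        # the virtual bands sit at left rows + 5: the lane model must equal a
        # direct fit of that shifted assignment at the same order
        shifted = PeakAssignment(
            list(zip(left.bp, left.rows + 5.0)), lane_center_col=50.0
        )
        direct = fit_calibration(shifted, force_order=model.order)
        grid = np.linspace(150, 350, 40)
        np.testing.assert_allclose(model(grid), direct(grid), rtol=1e-9)

    def test_swapping_markers_is_symmetric(self):
        left = self._assignment(0.0, 10.0)
        right = self._assignment(8.0, 200.0)
        lanes = [40.0, 110.0, 230.0]  # includes extrapolation beyond the right marker
        grid = np.linspace(120, 380, 40)
        for m1, m2 in zip(
            build_virtual_markers(left, right, lanes),
            build_virtual_markers(right, left, lanes),
        ):
            np.testing.assert_allclose(m1(grid), m2(grid), rtol=1e-9)

    def test_tilted_gel_recovers_true_lengths_within_one_percent(self, demo):
        recipe, truth = demo["recipe"], demo["truth"]
        ladder = recipe.ladders[0].ladder
        assignments = []
        for marker in demo["markers"]:
            peaks = detect_peaks(marker, 0.1)
            assignments.append(
                assign_ladder(peaks, ladder, lane_center_col=marker.lane_center_col)
            )
        lanes = demo["lanes"]
        models = build_virtual_markers(
            assignments[0], assignments[1], [p.lane_center_col for p in lanes]
        )
        offsets = recipe.tilt_rows * np.array(
            [p.lane_center_col for p in lanes]
        ) / (recipe.width - 1)
        for model, lane, off in zip(models, lanes, offsets):
            true_rows = recipe.migration.row_of(np.asarray(ladder.fragments_bp)) + off
            pred = model.predict_length(true_rows)
            np.testing.assert_allclose(pred, ladder.fragments_bp, rtol=0.01)

    def test_too_few_shared_fragments_rejected(self):
        left = self._assignment(0.0, 10.0, bp=np.array([8000.0, 6000, 4000]))
        right = self._assignment(0.0, 200.0, bp=np.array([3000.0, 2000, 1000]))
        with pytest.raises(ValueError, match="shared"):
            build_virtual_markers(left, right, [100.0])

    def test_identical_marker_columns_rejected(self):
        left = self._assignment(0.0, 10.0)
        right = self._assignment(5.0, 10.0)
        with pytest.raises(ValueError, match="column"):
            build_virtual_markers(left, right, [100.0])


def test_shipped_ladder_presets_are_valid():
    presets = load_ladder_presets()
    assert "lambda-hindiii" in presets and len(presets) >= 3
    for spec in presets.values():
        assert all(a > b for a, b in zip(spec.fragments_bp, spec.fragments_bp[1:]))
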