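"""Ground-truth construction and localization scores against brute-force oracles."""

import numpy as np
import pytest

from foveate.metrics import (
    GroundTruth,
    box_to_mask,
    contour_radius,
    dataset_report,
    energy_pointing_score,
    gaussian_heatmap,
    in_out_stats,
    iou_curve,
    keypoints_to_heatmap,
    pointing_game,
)
from foveate.saliency import fixation_grid

from conftest import FunctionClassifier, texture


def gt_from_mask(mask):
    return GroundTruth(mask=np.asarray(mask, dtype=bool),
                       heatmap=np.asarray(mask, dtype=float))


class TestBoxToMask:
    def test_full_frame_box_covers_grid(self):
        mask = box_to_mask((-1, -1, 1, 1), 11)
        assert mask.sum() == 121

    def test_subcell_central_box_marks_center_only(self):
        mask = box_to_mask((-1 / 11, -1 / 11, 1 / 11, 1 / 11), 11)
        assert mask.sum() == 1
        assert mask[5, 5]

    def test_left_half_plane_includes_boundary_column(self):
        mask = box_to_mask((-1, -1, 0, 1), 11)
        # columns at x in {-1, -0.8, ..., 0}: 6 of 11
        assert np.array_equal(mask.sum(axis=0), [11] * 6 + [0] * 5)

    def test_tiny_offgrid_box_marks_nearest_cell(self):
        mask = box_to_mask((0.28, -0.52, 0.33, -0.47), 11)
        assert mask.sum() == 1
        fixes = fixation_grid(11)
        r, c = np.argwhere(mask)[0]
        np.testing.assert_allclose(fixes[r, c], [0.4, -0.4], atol=1e-12)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            box_to_mask((0.5, 0.0, 0.5, 0.2), 11)

    def test_coverage_rule_counts_half_covered_cells(self):
        # the left half-plane box covers exactly half of the boundary
        # column's cells, so they are inside at min_coverage 0.5 and
        # excluded just above it
        mask_in = box_to_mask((-1, -1, 0, 1), 11, rule="coverage",
                              min_coverage=0.5)
        mask_out = box_to_mask((-1, -1, 0, 1), 11, rule="coverage",
                               min_coverage=0.51)
        assert np.array_equal(mask_in.sum(axis=0), [11] * 6 + [0] * 5)
        assert np.array_equal(mask_out.sum(axis=0), [11] * 5 + [0] * 6)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            box_to_mask((-1, -1, 1, 1), 11, rule="area")


class TestKeypointHeatmap:
    def test_peak_value_is_one_at_keypoint(self):
        v = gaussian_heatmap(np.array([[0.2, -0.1]]), 0.1,
                             np.array(0.2), np.array(-0.1))
        assert v == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        v = gaussian_heatmap(np.array([[0.0, 0.0]]), 0.25,
                             np.array(0.25), np.array(0.0))
        assert v == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_contour_radius_closed_form(self):
        sigma = 0.17
        assert contour_radius(sigma, 0.2) == pytest.approx(
            sigma * np.sqrt(2 * np.log(5)), abs=1e-12)
        # and the Gaussian indeed crosses 0.2 there
        r = contour_radius(sigma, 0.2)
        v = gaussian_heatmap(np.array([[0.0, 0.0]]), sigma, np.array(r), np.array(0.0))
        assert v == pytest.approx(0.2, abs=1e-12)

    def test_multi_keypoint_max_keeps_unit_peak(self):
        pts = [[-0.3, 0.0], [0.3, 0.0]]
        gt = keypoints_to_heatmap(pts, object_scale=0.6, grid_size=11)
        assert gt.heatmap.max() == pytest.approx(1.0)
        assert gt.mask.any()
        assert gt.source == "keypoints"

    def test_downsampled_mask_covers_keypoint_cell(self):
        gt = keypoints_to_heatmap([[0.4, 0.4]], object_scale=0.5, grid_size=11)
        assert gt.mask[7, 7]  # fixation (0.4, 0.4)

    def test_no_keypoints_rejected(self):
        with pytest.raises(ValueError):
            keypoints_to_heatmap([], grid_size=11)


class TestPointingGame:
    def test_center_peak_in_full_mask(self):
        values = np.zeros((11, 11))
        values[5, 5] = 1.0
        assert pointing_game(values, gt_from_mask(np.ones((11, 11))))

    def test_flat_map_tie_breaks_row_major(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 0] = False
        assert not pointing_game(np.full((3, 3), 0.5), gt_from_mask(mask))

    def test_all_peak_positions_enumerated(self):
        rng = np.random.default_rng(0)
        for pr in range(3):
            for pc in range(3):
                values = rng.random((3, 3)) * 0.5
                values[pr, pc] = 0.9
                mask = rng.random((3, 3)) > 0.4
                mask[1, 1] = True  # never empty
                assert pointing_game(values, gt_from_mask(mask)) == bool(mask[pr, pc])

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.5
        mask[2, 2] = True
        gt = gt_from_mask(mask)
        assert pointing_game(values, gt) == pointing_game(values ** 3, gt)
        assert pointing_game(values, gt) == pointing_game(0.1 + 0.5 * values, gt)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pointing_game(np.ones((3, 3)), gt_from_mask(np.zeros((3, 3))))


class TestInOutStats:
    def test_constant_map_has_unit_ratio(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True
        mean_in, mean_out, ratio = in_out_stats(np.full((5, 5), 0.3),
                                                gt_from_mask(mask))
        assert mean_in == pytest.approx(0.3)
        assert mean_out == pytest.approx(0.3)
        assert ratio == pytest.approx(1.0)

    def test_map_equal_to_mask_flags_undefined_ratio(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        mean_in, mean_out, ratio = in_out_stats(mask.astype(float),
                                                gt_from_mask(mask))
        assert mean_in == 1.0
        assert mean_out == 0.0
        assert np.isnan(ratio)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((11, 11))
        mask = rng.random((11, 11)) > 0.5
        mask[3, 3] = True
        mask[7, 7] = False
        mean_in, mean_out, ratio = in_out_stats(values, gt_from_mask(mask))
        s_in = n_in = s_out = n_out = 0
        for r in range(11):
            for c in range(11):
                if mask[r, c]:
                    s_in += values[r, c]
                    n_in += 1
                else:
                    s_out += values[r, c]
                    n_out += 1
        assert mean_in == pytest.approx(s_in / n_in, abs=1e-15)
        assert mean_out == pytest.approx(s_out / n_out, abs=1e-15)
        assert ratio == pytest.approx((s_in / n_in) / (s_out / n_out), abs=1e-12)


class TestIoU:
    def test_perfect_map_has_unit_iou(self):
        rng = np.random.default_rng(0)
        mask = rng.random((11, 11)) > 0.5
        mask[0, 0] = True
        _, ious, peak, _ = iou_curve(mask.astype(float), gt_from_mask(mask),
                                     thresholds=[0.5, 1.0])
        np.testing.assert_array_equal(ious, 1.0)
        assert peak == 1.0

    def test_all_ones_map_iou_is_mask_fraction(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask.ravel()[:40] = True
        _, ious, _, _ = iou_curve(np.ones((11, 11)), gt_from_mask(mask),
                                  thresholds=[0.5])
        assert ious[0] == pytest.approx(40 / 121)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_set_based_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        values = rng.random((11, 11))
        mask = rng.random((11, 11)) > 0.6
        mask[5, 5] = True
        thresholds = np.linspace(0, 1, 21)
        _, ious, peak, peak_thr = iou_curve(values, gt_from_mask(mask), thresholds)
        mask_cells = {(r, c) for r in range(11) for c in range(11) if mask[r, c]}
        expected = []
        for t in thresholds:
            bin_cells = {(r, c) for r in range(11) for c in range(11)
                         if values[r, c] >= t}
            union = bin_cells | mask_cells
            inter = bin_cells & mask_cells
            expected.append(len(inter) / len(union) if union else 0.0)
        np.testing.assert_array_equal(ious, expected)
        assert peak == max(expected)
        assert peak_thr == thresholds[int(np.argmax(expected))]

    def test_iou_symmetric_in_sets(self):
        rng = np.random.default_rng(3)
        a = rng.random((7, 7)) > 0.5
        b = rng.random((7, 7)) > 0.5
        a[0, 0] = b[1, 1] = True
        _, iou_ab, _, _ = iou_curve(a.astype(float), gt_from_mask(b), [0.5])
        _, iou_ba, _, _ = iou_curve(b.astype(float), gt_from_mask(a), [0.5])
        assert iou_ab[0] == iou_ba[0]

    def test_out_of_range_thresholds_rejected(self):
        with pytest.raises(ValueError):
            iou_curve(np.ones((3, 3)), gt_from_mask(np.ones((3, 3))), [1.5])


class TestEnergyScore:
    def test_is_mass_fraction(self):
        values = np.zeros((3, 3))
        values[0, 0] = 0.6
        values[2, 2] = 0.2
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        assert energy_pointing_score(values, gt_from_mask(mask)) == pytest.approx(0.75)


class TestDatasetReport:
    def test_single_successful_image_has_unit_rate(self):
        clf = FunctionClassifier(seed=0)
        img = texture(0)
        gt = gt_from_mask(np.ones((5, 5)))  # full-frame mask: pointing succeeds
        rep = dataset_report(clf, [img], [0], [gt], grid_size=5)
        assert rep.pointing_rate == 1.0
        assert len(rep.per_image) == 1
        assert rep.accuracy_improvement == rep.saccade_accuracy - rep.central_accuracy

    def test_rate_is_mean_of_booleans(self):
        clf = FunctionClassifier(seed=1)
        images = [texture(s) for s in range(4)]
        masks = []
        rng = np.random.default_rng(5)
        for _ in images:
            m = rng.random((5, 5)) > 0.4
            m[2, 2] = True
            masks.append(gt_from_mask(m))
        rep = dataset_report(clf, images, [0, 1, 2, 3], masks, grid_size=5)
        assert rep.pointing_rate == pytest.approx(rep.per_image["pointing"].mean())

    def test_misaligned_collections_rejected(self):
        clf = FunctionClassifier()
        with pytest.raises(ValueError):
            dataset_report(clf, [texture(0)], [0, 1],
                           [gt_from_mask(np.ones((5, 5)))], grid_size=5)
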