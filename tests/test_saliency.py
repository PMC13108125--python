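"""Fixation grids, per-fixation crops, likelihood maps and map aggregation."""

import numpy as np
import pytest

from foveate.saliency import (
    AggregateMaps,
    LikelihoodMap,
    crop_at_fixation,
    crop_radius,
    fixation_grid,
    likelihood_map,
    map_algebra,
    multi_label_maps,
    peak_cell,
    recenter_and_aggregate,
    saccade_and_classify,
)

from conftest import ConstantClassifier, FunctionClassifier, texture


class TestFixationGrid:
    def test_single_point_is_center(self):
        np.testing.assert_array_equal(fixation_grid(1), np.zeros((1, 1, 2)))

    def test_eleven_grid_center_cell(self):
        g = fixation_grid(11)
        np.testing.assert_allclose(g[5, 5], [0.0, 0.0], atol=1e-15)

    def test_three_grid_corners(self):
        g = fixation_grid(3)
        np.testing.assert_array_equal(g[0, 0], [-1, -1])
        np.testing.assert_array_equal(g[2, 2], [1, 1])
        np.testing.assert_array_equal(g[0, 2], [1, -1])  # (x, y) order

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            fixation_grid(0)


class TestCrop:
    def test_radius_rule_endpoints_and_interior(self):
        assert crop_radius((0.0, 0.0)) == 1.0
        assert crop_radius((1.0, 1.0)) == 0.1
        assert crop_radius((0.5, 0.0)) == 0.5
        assert crop_radius((0.0, -0.8)) == pytest.approx(0.2)

    def test_fixation_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            crop_radius((1.5, 0.0))

    def test_invalid_min_ratio(self):
        with pytest.raises(ValueError):
            crop_radius((0, 0), min_ratio=0.0)

    def test_constant_image_crop_is_constant(self):
        img = np.full((1, 64, 64), 0.4)
        crop, r = crop_at_fixation(img, (0.3, -0.2), out_size=(32, 32))
        assert r == pytest.approx(0.7)
        np.testing.assert_allclose(crop, 0.4, atol=1e-12)

    def test_corner_crop_fills_outside(self):
        img = np.ones((1, 64, 64))
        crop, r = crop_at_fixation(img, (1.0, 1.0), out_size=(20, 20))
        assert r == 0.1
        # the crop square [0.9, 1.1]^2 extends outside the frame: the lower
        # right part must be fill, the upper left part ones
        assert crop[0, 0, 0] == 1.0
        assert crop[0, -1, -1] == 0.0


class TestLikelihoodMap:
    def test_constant_classifier_gives_flat_map(self):
        clf = ConstantClassifier([0.2, 0.5, 0.3])
        lm = likelihood_map(clf, texture(0), 1, grid_size=5)
        np.testing.assert_array_equal(lm.values, 0.5)
        assert lm.values.shape == (5, 5)

    def test_single_batched_classifier_call(self):
        calls = []

        class Counting(ConstantClassifier):
            def predict(self, batch):
                calls.append(len(batch))
                return super().predict(batch)

        clf = Counting([0.5, 0.5])
        likelihood_map(clf, texture(1), 0, grid_size=7)
        assert calls == [49]

    def test_values_bounded(self):
        clf = FunctionClassifier(seed=1)
        lm = likelihood_map(clf, texture(2), 0, grid_size=5)
        assert np.all(lm.values >= 0) and np.all(lm.values <= 1)

    def test_matches_per_fixation_scalar_evaluation(self):
        # batching must not change any cell (order invariance)
        clf = FunctionClassifier(seed=3)
        img = texture(3)
        lm = likelihood_map(clf, img, 2, grid_size=5)
        for r in range(5):
            for c in range(5):
                fx, fy = lm.fixations[r, c]
                crop, _ = crop_at_fixation(img, (fx, fy),
                                           out_size=clf.input_resolution)
                p = clf.predict(crop[None])[0][2]
                assert lm.values[r, c] == p

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            likelihood_map(ConstantClassifier([1.0]), texture(0), 3, grid_size=3)


class TestMultiLabel:
    def test_single_label_equals_likelihood_map(self):
        clf = FunctionClassifier(seed=5)
        img = texture(4)
        single = likelihood_map(clf, img, 1, grid_size=5)
        multi = multi_label_maps(clf, img, [1], grid_size=5)
        np.testing.assert_array_equal(single.values, multi[0].values)

    def test_maps_sum_to_one_over_all_labels(self):
        clf = FunctionClassifier(n_classes=4, seed=6)
        maps = multi_label_maps(clf, texture(5), [0, 1, 2, 3], grid_size=5)
        total = sum(m.values for m in maps)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            multi_label_maps(FunctionClassifier(), texture(0), [1, 1])


class TestSaccade:
    def test_grid_one_equals_central_classification(self):
        clf = FunctionClassifier(seed=7)
        img = texture(6)
        fix, probs, correct = saccade_and_classify(clf, img, 0, grid_size=1)
        crop, _ = crop_at_fixation(img, (0.0, 0.0), out_size=clf.input_resolution)
        expected = clf.predict(crop[None])[0]
        assert fix == (0.0, 0.0)
        np.testing.assert_array_equal(probs, expected)
        assert correct == (int(np.argmax(expected)) == 0)


def make_map(values):
    g = values.shape[0]
    return LikelihoodMap(values=np.asarray(values, dtype=float),
                         fixations=fixation_grid(g),
                         crop_radii=np.ones((g, g)), label=0, mode="cartesian")


class TestAggregate:
    def test_center_peaked_map_is_copied_with_nan_border(self):
        rng = np.random.default_rng(0)
        values = rng.random((5, 5)) * 0.5
        values[2, 2] = 0.9
        agg = recenter_and_aggregate([make_map(values)])
        assert agg.values.shape == (9, 9)
        np.testing.assert_array_equal(agg.values[2:7, 2:7], values)
        assert np.isnan(agg.values[0, 0])
        assert not agg.valid[0, 0]

    def test_central_cell_is_mean_of_peaks(self):
        rng = np.random.default_rng(1)
        maps = []
        for _ in range(6):
            v = rng.random((5, 5))
            maps.append(make_map(v))
        agg = recenter_and_aggregate(maps)
        expected = np.mean([m.values.max() for m in maps])
        assert agg.values[4, 4] == pytest.approx(expected)
        # the canvas maximum sits at the center cell
        assert np.nanmax(agg.values) == pytest.approx(agg.values[4, 4])

    def test_coverage_counts_match_enumeration(self):
        rng = np.random.default_rng(2)
        maps = [make_map(rng.random((3, 3))) for _ in range(10)]
        agg = recenter_and_aggregate(maps)
        # scalar enumeration over all peak positions
        expected = np.zeros((5, 5), dtype=int)
        for m in maps:
            pr, pc = peak_cell(m.values)
            for r in range(3):
                for c in range(3):
                    expected[2 - pr + r, 2 - pc + c] += 1
        np.testing.assert_array_equal(agg.counts, expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            recenter_and_aggregate([])


class TestMapAlgebra:
    def make_agg(self, values):
        values = np.asarray(values, dtype=float)
        counts = np.where(np.isnan(values), 0, 1).astype(np.intp)
        g = (values.shape[0] + 1) // 2
        return AggregateMaps(values=values, counts=counts, grid_size=g)

    def test_equal_maps_give_zero(self):
        a = self.make_agg(np.full((3, 3), 0.4))
        diff, lo = map_algebra(a, a)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)
        np.testing.assert_allclose(lo, 0.0, atol=1e-12)

    def test_half_probability_has_zero_logit(self):
        a = self.make_agg(np.full((3, 3), 0.5))
        b = self.make_agg(np.full((3, 3), 0.8))
        _, lo = map_algebra(a, b)
        expected = -np.log(0.8 / 0.2)
        np.testing.assert_allclose(lo, expected, atol=1e-6)

    def test_clamped_logit_value(self):
        a = self.make_agg(np.full((3, 3), 1.0))
        b = self.make_agg(np.full((3, 3), 0.5))
        _, lo = map_algebra(a, b, eps=1e-6)
        assert lo[0, 0] == pytest.approx(13.8155, abs=5e-4)

    def test_undefined_cells_propagate(self):
        va = np.full((3, 3), 0.5)
        va[0, 0] = np.nan
        a = self.make_agg(va)
        b = self.make_agg(np.full((3, 3), 0.5))
        diff, lo = map_algebra(a, b)
        assert np.isnan(diff[0, 0]) and np.isnan(lo[0, 0])
        assert diff[1, 1] == 0.0

    def test_shape_mismatch_rejected(self):
        a = self.make_agg(np.full((3, 3), 0.5))
        b = self.make_agg(np.full((5, 5), 0.5))
        with pytest.raises(ValueError):
            map_algebra(a, b)


class TestPlantedObjectDirection:
    def test_bright_object_in_left_half_pulls_argmax_left(self):
        # analytic "classifier": label-0 likelihood grows with the crop's
        # central brightness, so fixating the planted bright blob wins
        class CenterBrightness:
            input_mode = "cartesian"
            input_resolution = (32, 32)

            def predict(self, batch):
                n, c, h, w = batch.shape
                center = batch[:, :, h // 4: 3 * h // 4, w // 4: 3 * w // 4]
                m = np.clip(center.mean(axis=(1, 2, 3)) ** 2 * 4, 1e-6, 1 - 1e-6)
                return np.stack([m, 1 - m], axis=1)

        clf = CenterBrightness()
        hits = 0
        n_scenes = 20
        for seed in range(n_scenes):
            rng = np.random.default_rng(seed)
            img = np.full((1, 64, 64), 0.1)
            # plant a bright square in the left half
            cx = rng.uniform(-0.6, -0.3)
            cy = rng.uniform(-0.4, 0.4)
            col = int((cx + 1) * 32)
            row = int((cy + 1) * 32)
            img[0, max(row - 5, 0):row + 5, max(col - 5, 0):col + 5] = 1.0
            lm = likelihood_map(clf, img, 0, grid_size=11)
            _, c = peak_cell(lm.values)
            if c < 5.5:
                hits += 1
        assert hits >= 0.9 * n_scenes
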