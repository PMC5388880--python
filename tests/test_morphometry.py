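"""Pixel-ratio morphometry: coverage, detachment, plaque load, thresholding."""

import numpy as np
import pytest

from neurovasc.morphometry import (LabeledMask, class_pixel_fraction,
                                   coverage_fraction, detachment_fraction,
                                   plaque_load, threshold_by_background,
                                   vascular_amyloid_load)


def binmask(arr, px=1.0):
    return LabeledMask(np.asarray(arr, dtype=np.uint8), px)


def flood_fill_label(mask):
    """Independent 8-connectivity component labeling by explicit flood fill."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels, current


class TestCoverage:
    def test_identical_masks_full_coverage(self):
        m = np.zeros((20, 20)); m[5:10, 5:10] = 1
        assert coverage_fraction(binmask(m), binmask(m)).value == 1.0

    def test_empty_signal_zero(self):
        ref = np.zeros((20, 20)); ref[2:8, 2:8] = 1
        assert coverage_fraction(binmask(np.zeros((20, 20))), binmask(ref)).value == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coverage_fraction(binmask(np.ones((5, 5))), binmask(np.zeros((5, 5))))

    def test_invariant_to_common_cropping(self):
        rng = np.random.default_rng(0)
        sig = np.zeros((64, 64), dtype=np.uint8)
        ref = np.zeros((64, 64), dtype=np.uint8)
        ref[10:50, 10:50] = 1
        sig[10:50, 10:50] = rng.integers(0, 2, (40, 40))
        full = coverage_fraction(binmask(sig), binmask(ref)).value
        cropped = coverage_fraction(binmask(sig[5:55, 5:55]), binmask(ref[5:55, 5:55])).value
        assert full == cropped


class TestDetachment:
    def test_touching_instances_not_detached(self):
        m = np.zeros((10, 10), dtype=np.int32)
        m[2:4, 2:4] = 1
        m[2:4, 4:6] = 2  # shares an edge with 1
        assert detachment_fraction(LabeledMask(m, 1.0)).value == 0.0

    def test_far_apart_instances_fully_detached(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[2:4, 2:4] = 1
        m[10:12, 10:12] = 2
        assert detachment_fraction(LabeledMask(m, 1.0)).value == 1.0

    def test_diagonal_touch_counts_as_contact(self):
        m = np.zeros((10, 10), dtype=np.int32)
        m[2:4, 2:4] = 1
        m[4:6, 4:6] = 2  # corner contact
        assert detachment_fraction(LabeledMask(m, 1.0)).value == 0.0

    def test_monotone_nonincreasing_in_contact_distance(self):
        m = np.zeros((30, 30), dtype=np.int32)
        m[2:5, 2:5] = 1
        m[2:5, 8:11] = 2   # 3 px gap
        m[20:23, 20:23] = 3
        mask = LabeledMask(m, 1.0)
        vals = [detachment_fraction(mask, contact_distance=d).value for d in (1, 3, 5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_single_instance_warns_and_returns_one(self):
        m = np.zeros((10, 10), dtype=np.int32); m[2:5, 2:5] = 1
        with pytest.warns(UserWarning, match="single"):
            assert detachment_fraction(LabeledMask(m, 1.0)).value == 1.0


class TestClassFraction:
    def test_all_none_and_half_flagged(self):
        m = np.zeros((10, 20), dtype=np.int32)
        m[2:4, 2:4] = 1
        m[2:4, 10:12] = 2
        mask = LabeledMask(m, 1.0)
        assert class_pixel_fraction(mask, {1: True, 2: True}).value == 1.0
        assert class_pixel_fraction(mask, {1: False, 2: False}).value == 0.0
        assert class_pixel_fraction(mask, {1: True, 2: False}).value == 0.5

    def test_missing_flag_rejected(self):
        m = np.zeros((10, 10), dtype=np.int32); m[1:3, 1:3] = 1; m[5:7, 5:7] = 2
        with pytest.raises(ValueError, match="missing"):
            class_pixel_fraction(LabeledMask(m, 1.0), {1: True})


class TestPlaqueLoad:
    def test_single_plaque_percent_of_roi(self):
        roi = np.ones((100, 100), dtype=np.uint8)
        plq = np.zeros((100, 100), dtype=np.uint8)
        plq[10:30, 10:35] = 1  # 500 px
        res, count = plaque_load(binmask(plq), binmask(roi), min_plaque_area=100.0)
        assert res.value == pytest.approx(5.0)
        assert count == 1

    def test_minimum_area_filters_small_components(self):
        roi = np.ones((100, 100), dtype=np.uint8)
        plq = np.zeros((100, 100), dtype=np.uint8)
        plq[5:10, 5:15] = 1      # 50 px
        plq[20:30, 20:30] = 1    # 100 px
        plq[50:70, 50:70] = 1    # 400 px
        res, count = plaque_load(binmask(plq), binmask(roi), min_plaque_area=100.0)
        assert count == 2
        assert res.numerator_pixels == 500
        res0, count0 = plaque_load(binmask(plq), binmask(roi), min_plaque_area=0.0)
        assert count0 == 3 and res0.numerator_pixels == 550

    def test_count_and_area_nonincreasing_in_min_area(self):
        rng = np.random.default_rng(1)
        plq = (rng.random((64, 64)) > 0.7).astype(np.uint8)
        roi = np.ones((64, 64), dtype=np.uint8)
        prev_count, prev_px = np.inf, np.inf
        for min_area in (0.0, 2.0, 5.0, 10.0, 50.0):
            res, count = plaque_load(binmask(plq), binmask(roi), min_area)
            assert count <= prev_count and res.numerator_pixels <= prev_px
            prev_count, prev_px = count, res.numerator_pixels

    def test_component_labeling_agrees_with_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        roi = np.ones((64, 64), dtype=np.uint8)
        for _ in range(50):
            plq = (rng.random((64, 64)) > 0.75).astype(np.uint8)
            _, n_oracle = flood_fill_label(plq)
            _, count = plaque_load(binmask(plq), binmask(roi), min_plaque_area=0.0)
            assert count == n_oracle

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            plaque_load(binmask(np.ones((5, 5))), binmask(np.zeros((5, 5))))


class TestVascularAmyloid:
    @pytest.mark.parametrize("amy,ves,expected", [
        (39.0, 100.0, 39.0), (0.0, 100.0, 0.0), (10.5, 100.0, 10.5),
    ])
    def test_surface_ratio_percent(self, amy, ves, expected):
        assert vascular_amyloid_load(amy, ves) == pytest.approx(expected)

    def test_inconsistent_segmentation_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            vascular_amyloid_load(120.0, 100.0)


class TestBackgroundThreshold:
    def test_zero_background_thresholds_at_minimum_positive(self):
        img = np.zeros((50, 50)); img[10:20, 10:20] = 7.0
        bg = np.zeros((50, 50), bool); bg[30:, :] = True
        mask, th = threshold_by_background(img, bg, pixel_size=1.0, target_density=8.0)
        assert th == 0.0
        assert mask.pixels.sum() == 100

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 40, (80, 80)).astype(float)
        bg = np.zeros((80, 80), bool); bg[:25] = True
        _, th = threshold_by_background(img, bg, pixel_size=1.0, target_density=9.0)
        allowed = 9.0 * bg.sum() / 150.0
        feasible = [t for t in np.unique(img[bg])
                    if (img[bg] > t).sum() <= allowed]
        assert th == min(feasible)
        assert (img[bg] > th - 1e-9).sum() > allowed  # smallest: one step down fails

    def test_threshold_monotone_in_target_density(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 40, (80, 80)).astype(float)
        bg = np.zeros((80, 80), bool); bg[:25] = True
        ths = [threshold_by_background(img, bg, 1.0, d)[1] for d in (10.0, 8.0, 4.0, 1.0)]
        assert all(a <= b for a, b in zip(ths, ths[1:]))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_by_background(np.ones((5, 5)), np.zeros((5, 5), bool), 1.0)
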