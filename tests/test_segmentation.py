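"""Adaptive inverse thresholding, mask cleanup and mitosis flagging."""

import math

import numpy as np
import pytest

from celldrift.segmentation import (
    SegmentationParams,
    adaptive_threshold,
    circle_support_score,
    clean_mask,
    detect_mitotic,
    fit_circle,
    segment_stack,
)
from tests.conftest import match_detections


def brute_force_gaussian_mean(img, window):
    """Independent local-mean oracle: explicit truncated-Gaussian convolution
    with reflect padding, sigma = (window - 1) / 6 as for a Gaussian window."""
    sigma = (window - 1) / 6.0
    half = window // 2
    ax = np.arange(-half, half + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(k1, k1)
    k /= k.sum()
    pad = np.pad(img.astype(float), half, mode="reflect")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (pad[i : i + window, j : j + window] * k).sum()
    return out


class TestAdaptiveThreshold:
    def test_uniform_image_gives_empty_mask(self):
        img = np.full((50, 50), 137, dtype=np.uint8)
        mask = adaptive_threshold(img, SegmentationParams(threshold_offset=1.0))
        assert not mask.any()

    def test_single_dark_disk_yields_one_component(self):
        img = np.full((80, 80), 200.0)
        rr, cc = np.mgrid[0:80, 0:80]
        img[(rr - 40) ** 2 + (cc - 40) ** 2 <= 64] = 120.0
        mask = adaptive_threshold(img, SegmentationParams())
        from skimage.measure import label

        assert label(mask).max() == 1
        # the disk interior (eroded by boundary effects) is fully detected
        core = (rr - 40) ** 2 + (cc - 40) ** 2 <= 25
        assert mask[core].all()

    def test_checkerboard_against_convolution_oracle(self):
        # period 4 << window 21: both phases sit near the local mean,
        # dark phase below it, bright phase above
        tile = np.kron([[0, 1] * 6, [1, 0] * 6] * 6, np.ones((2, 2)))
        img = 150 + 40 * tile[:42, :42]
        p = SegmentationParams(gaussian_window=21, threshold_offset=2.0)
        mask = adaptive_threshold(img, p)
        assert mask.any()
        oracle_mean = brute_force_gaussian_mean(img, 21)
        oracle_mask = img < oracle_mean - p.threshold_offset
        # compare only where the classification is unambiguous: the two
        # Gaussian truncations differ slightly in the far tails
        confident = np.abs(img - (oracle_mean - p.threshold_offset)) > 2.0
        assert (mask == oracle_mask)[confident].all()
        assert oracle_mask[confident].any()

    def test_bright_polarity_switch(self):
        img = np.full((60, 60), 100.0)
        rr, cc = np.mgrid[0:60, 0:60]
        disk = (rr - 30) ** 2 + (cc - 30) ** 2 <= 49
        img[disk] = 180.0
        dark = adaptive_threshold(img, SegmentationParams())
        bright = adaptive_threshold(img, SegmentationParams(dark_cells=False))
        assert not dark[disk].any()
        assert bright[rr[disk], cc[disk]].sum() > 0.8 * disk.sum()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((20, 20)), SegmentationParams(gaussian_window=33))

    @pytest.mark.parametrize("offsets", [(0.5, 2.0, 8.0, 20.0)])
    def test_foreground_shrinks_monotonically_with_offset(self, offsets):
        rng = np.random.default_rng(0)
        img = rng.normal(128, 20, size=(60, 60))
        counts = [
            adaptive_threshold(img, SegmentationParams(threshold_offset=o)).sum()
            for o in offsets
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def brute_force_erode(mask, radius):
    """Set-definition morphology oracle: a pixel survives erosion iff every
    pixel of the disk footprint centred there is foreground."""
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    h, w = mask.shape
    r = radius
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + 2 * r + 1, j : j + 2 * r + 1][fp].all()
    return out


def brute_force_dilate(mask, radius):
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    h, w = mask.shape
    r = radius
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + 2 * r + 1, j : j + 2 * r + 1][fp].any()
    return out


class TestCleanMask:
    def test_single_pixel_specks_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5, 5] = mask[20, 33] = True
        p = SegmentationParams(erode_radius=1, dilate_radius=1, min_area=5)
        assert not clean_mask(mask, p).any()

    def test_bridged_disks_detach(self):
        mask = np.zeros((40, 80), dtype=bool)
        rr, cc = np.mgrid[0:40, 0:80]
        mask[(rr - 20) ** 2 + (cc - 20) ** 2 <= 64] = True
        mask[(rr - 20) ** 2 + (cc - 60) ** 2 <= 64] = True
        mask[20, 20:61] = True  # 1-px bridge
        from skimage.measure import label

        cleaned = clean_mask(mask, SegmentationParams(min_area=20))
        assert label(cleaned).max() == 2

    def test_large_disk_area_stable_and_matches_set_oracle(self):
        mask = np.zeros((80, 80), dtype=bool)
        rr, cc = np.mgrid[0:80, 0:80]
        mask[(rr - 40) ** 2 + (cc - 40) ** 2 <= 15**2] = True
        p = SegmentationParams(erode_radius=2, dilate_radius=2, min_area=20, max_area=5000)
        cleaned = clean_mask(mask, p)
        oracle = brute_force_dilate(brute_force_erode(mask, 2), 2)
        assert np.array_equal(cleaned, oracle)
        assert abs(cleaned.sum() - mask.sum()) <= 0.1 * mask.sum()

    def test_empty_in_empty_out(self):
        assert not clean_mask(np.zeros((30, 30), dtype=bool), SegmentationParams()).any()


class TestDetectMitotic:
    def _raster_disk(self, shape, center, radius):
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2

    def test_circle_in_size_range_flagged(self):
        from skimage.measure import label

        m = self._raster_disk((60, 60), (30, 30), 12)
        flags = detect_mitotic(label(m), SegmentationParams())
        assert flags == {1: True}

    def test_circle_outside_size_range_not_flagged(self):
        from skimage.measure import label

        m = self._raster_disk((60, 60), (30, 30), 6)
        flags = detect_mitotic(label(m), SegmentationParams())
        assert flags == {1: False}

    def test_elongated_ellipse_scores_below_threshold(self):
        # 3:1 ellipse with the same area as a radius-12 circle
        from skimage.draw import ellipse
        from skimage.measure import label
        from skimage.segmentation import find_boundaries

        a, b = 12 * math.sqrt(3), 12 / math.sqrt(3)
        m = np.zeros((80, 80), dtype=bool)
        rr, cc = ellipse(40, 40, b, a)
        m[rr, cc] = True
        boundary = np.argwhere(find_boundaries(m, mode="inner")).astype(float)
        rc, cc_, rad = fit_circle(boundary)
        score = circle_support_score(boundary, (rc, cc_), rad)
        # independent brute-force recomputation of the perimeter support
        n = max(32, int(np.ceil(2 * np.pi * rad)))
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([rc + rad * np.sin(ang), cc_ + rad * np.cos(ang)])
        dmin = np.sqrt(((pts[:, None, :] - boundary[None, :, :]) ** 2).sum(-1)).min(1)
        assert score == pytest.approx(np.mean(dmin <= 1.5), abs=1e-12)
        assert score < 0.6
        assert detect_mitotic(label(m), SegmentationParams()) == {1: False}


class TestSegmentStack:
    def test_noiseless_stack_recovers_ground_truth_counts(self, spread_truth, clean_stack, seg_params):
        dets = segment_stack(clean_stack, seg_params)
        for f, d in enumerate(dets):
            assert len(d) == len(spread_truth.live_positions(f))

    def test_detection_quality_at_snr5(self, spread_truth, noisy_stack, seg_params):
        dets = segment_stack(noisy_stack, seg_params)
        recall, precision, err = match_detections(spread_truth, dets)
        assert recall >= 0.95
        assert precision >= 0.95
        assert err < 2.0

    def test_determinism(self, noisy_stack, seg_params):
        a = segment_stack(noisy_stack, seg_params)
        b = segment_stack(noisy_stack, seg_params)
        assert [(d.centroid, d.area) for f in a for d in f] == [
            (d.centroid, d.area) for f in b for d in f
        ]

    def test_dropout_frame_has_one_fewer_detection(self):
        from celldrift.synthetic import RenderParams, WalkerParams, render_stack, simulate_tracks

        wp = WalkerParams(
            n_cells=8, n_frames=20, step_sd=1.0, field_width=400.0,
            field_height=300.0, min_separation=60.0, seed=21,
        )
        truth = simulate_tracks(wp)
        stack = render_stack(truth, RenderParams(noise_sd=0.0, dropout_rate=0.08), seed=22)
        assert truth.dropout_events
        dets = segment_stack(stack, SegmentationParams())
        for f in range(wp.n_frames):
            dropped = sum(1 for (_, ff) in truth.dropout_events if ff == f)
            assert len(dets[f]) == len(truth.live_positions(f)) - dropped
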