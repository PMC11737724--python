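"""Hair-removal stage against brute-force morphology/median oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from dermlesion.hair_removal import (
    HairRemovalConfig,
    HairRemover,
    LineSegment,
    detect_hair_edges,
    extract_hair_lines,
    median_inpaint,
    rasterize_hair_mask,
    refine_edge_map,
    remove_hair,
    to_grayscale,
)
from dermlesion.synthdata import HairSpec, SynthParams, generate_sample


class TestGrayscale:
    def test_channel_equal_image_unchanged(self):
        img = np.full((4, 4, 3), 100, dtype=np.uint8)
        assert np.array_equal(to_grayscale(img), np.full((4, 4), 100))

    def test_white_maps_to_max(self):
        assert to_grayscale(np.full((1, 1, 3), 255, dtype=np.uint8))[0, 0] == 255

    def test_hand_computed_luminance(self):
        img = np.array([[[200, 0, 0], [0, 200, 0]],
                        [[0, 0, 200], [50, 100, 150]]], dtype=np.uint8)
        expected = np.round([[0.299 * 200, 0.587 * 200],
                             [0.114 * 200,
                              0.299 * 50 + 0.587 * 100 + 0.114 * 150]])
        assert np.array_equal(to_grayscale(img), expected.astype(np.uint8))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            to_grayscale(np.zeros((0, 0, 3), dtype=np.uint8))


class TestEdges:
    def test_constant_image_has_no_edges(self):
        cfg = HairRemovalConfig()
        gray = np.full((32, 32), 128, dtype=np.uint8)
        assert not detect_hair_edges(gray, cfg).any()

    def test_dark_bar_edges_near_boundaries_only(self):
        cfg = HairRemovalConfig()
        gray = np.full((32, 32), 128, dtype=np.uint8)
        gray[14:18, :] = 20
        edges = detect_hair_edges(gray, cfg)
        rows = np.unique(np.argwhere(edges)[:, 0])
        assert len(rows) > 0
        # independent gradient scan: rows with a Sobel response near the bar
        grad = np.abs(np.diff(gray.astype(float), axis=0))
        active = set(np.unique(np.argwhere(grad > 20)[:, 0])) | \
            set(np.unique(np.argwhere(grad > 20)[:, 0] + 1))
        pad = {r + d for r in active for d in (-1, 0, 1)}
        assert set(rows) <= pad

    def test_bright_pixels_suppressed(self):
        cfg = HairRemovalConfig(bright_cutoff=200)
        gray = np.full((32, 32), 128, dtype=np.uint8)
        gray[14:18, :] = 250  # bright bar: edges on it must be excluded
        edges = detect_hair_edges(gray, cfg)
        assert not edges[gray > 200].any()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            HairRemovalConfig(canny_low=100, canny_high=50)


def naive_closing_then_erosion(mask, close_r, erode_r):
    """Set-algebra oracle: dilate then erode (closing), then erode."""
    def offsets(r):
        return [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
                if dr * dr + dc * dc <= r * r]

    def dilate(m, r):
        out = np.zeros_like(m)
        H, W = m.shape
        for (i, j) in np.argwhere(m):
            for dr, dc in offsets(r):
                if 0 <= i + dr < H and 0 <= j + dc < W:
                    out[i + dr, j + dc] = True
        return out

    def erode(m, r):
        out = np.zeros_like(m)
        H, W = m.shape
        for (i, j) in np.argwhere(m):
            # border: treat outside as True (same convention as the library)
            if all(m[i + dr, j + dc]
                   for dr, dc in offsets(r)
                   if 0 <= i + dr < H and 0 <= j + dc < W):
                out[i, j] = True
        return out

    out = erode(dilate(mask, close_r), close_r) if close_r else mask
    return erode(out, erode_r) if erode_r else out


class TestRefine:
    def test_empty_stays_empty(self):
        cfg = HairRemovalConfig()
        assert not refine_edge_map(np.zeros((16, 16), dtype=bool), cfg).any()

    def test_singleton_removed_by_erosion(self):
        cfg = HairRemovalConfig(erode_radius=1)
        m = np.zeros((16, 16), dtype=bool)
        m[8, 8] = True
        assert not refine_edge_map(m, cfg).any()

    def test_parallel_lines_gap_filled_matches_oracle(self):
        cfg = HairRemovalConfig(close_radius=2, erode_radius=1)
        m = np.zeros((16, 16), dtype=bool)
        m[6, 2:14] = True
        m[9, 2:14] = True  # 2-px gap between the lines
        refined = refine_edge_map(m, cfg)
        oracle = naive_closing_then_erosion(m, 2, 1)
        assert np.array_equal(refined, oracle)
        assert refined[7, 6] and refined[8, 6]  # gap interior filled

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            HairRemovalConfig(close_radius=-1)


class TestHoughLines:
    def test_empty_mask_yields_no_lines(self):
        cfg = HairRemovalConfig()
        assert extract_hair_lines(np.zeros((64, 64), dtype=bool), cfg) == []

    def test_recovers_drawn_segment_endpoints(self):
        cfg = HairRemovalConfig(min_line_len=20, max_line_len=200,
                                hough_threshold=10)
        m = np.zeros((80, 80), dtype=bool)
        from skimage.draw import line
        p0, p1 = (10, 10), (58, 46)  # length 60
        rr, cc = line(*p0, *p1)
        m[rr, cc] = True
        lines = extract_hair_lines(m, cfg, seed=0)
        assert lines
        best = min(lines, key=lambda s: min(
            np.hypot(s.p0[0] - p0[0], s.p0[1] - p0[1])
            + np.hypot(s.p1[0] - p1[0], s.p1[1] - p1[1]),
            np.hypot(s.p0[0] - p1[0], s.p0[1] - p1[1])
            + np.hypot(s.p1[0] - p0[0], s.p1[1] - p0[1])))
        d = min(np.hypot(best.p0[0] - p0[0], best.p0[1] - p0[1]),
                np.hypot(best.p0[0] - p1[0], best.p0[1] - p1[1]))
        assert d <= 3.0

    def test_short_segment_filtered(self):
        cfg = HairRemovalConfig(min_line_len=20, max_line_len=200,
                                hough_threshold=5)
        m = np.zeros((64, 64), dtype=bool)
        m[30, 20:30] = True  # length 10 < 20
        assert extract_hair_lines(m, cfg, seed=0) == []

    def test_length_filter_is_total(self):
        cfg = HairRemovalConfig()
        m = np.zeros((96, 96), dtype=bool)
        rng = np.random.default_rng(5)
        from skimage.draw import line
        for _ in range(6):
            a, b, c, d = rng.integers(5, 90, size=4)
            rr, cc = line(a, b, c, d)
            m[rr, cc] = True
        max_len = cfg.resolved_max_len(m.shape)
        for seg in extract_hair_lines(m, cfg, seed=1):
            assert cfg.min_line_len <= seg.length <= max_len


class TestRasterize:
    def test_empty_list(self):
        cfg = HairRemovalConfig()
        assert not rasterize_hair_mask([], (16, 16), cfg).any()

    def test_horizontal_line_exact_pixel_set(self):
        cfg = HairRemovalConfig(dilate_radius=0)
        seg = LineSegment((5, 2), (5, 11))
        mask = rasterize_hair_mask([seg], (16, 16), cfg)
        expected = np.zeros((16, 16), dtype=bool)
        expected[5, 2:12] = True  # independently enumerated raster pixels
        assert np.array_equal(mask, expected)

    def test_dilated_mask_superset_within_radius(self):
        seg = LineSegment((5, 2), (5, 11))
        base = rasterize_hair_mask([seg], (16, 16),
                                   HairRemovalConfig(dilate_radius=0))
        grown = rasterize_hair_mask([seg], (16, 16),
                                    HairRemovalConfig(dilate_radius=2))
        assert np.all(grown[base])
        dist = distance_transform_edt(~base)
        assert np.all(dist[grown] <= 2.0)

    def test_dilation_monotone_in_radius(self):
        seg = LineSegment((3, 1), (12, 14))
        prev = None
        for r in range(4):
            m = rasterize_hair_mask([seg], (16, 16),
                                    HairRemovalConfig(dilate_radius=r))
            if prev is not None:
                assert np.all(m[prev])
            prev = m

    def test_out_of_frame_endpoint_rejected(self):
        cfg = HairRemovalConfig()
        with pytest.raises(ValueError, match="outside frame"):
            rasterize_hair_mask([LineSegment((0, 0), (20, 20))], (16, 16), cfg)


def inpaint_oracle(image, mask, window):
    """Brute-force pass-by-pass median fill, written independently."""
    img = image.astype(float).copy()
    todo = mask.copy()
    known = ~mask
    h = window // 2
    H, W = mask.shape
    while todo.any():
        newly = []
        for r in range(H):
            for c in range(W):
                if not todo[r, c]:
                    continue
                vals = []
                for i in range(max(r - h, 0), min(r + h + 1, H)):
                    for j in range(max(c - h, 0), min(c + h + 1, W)):
                        if known[i, j]:
                            vals.append(img[i, j])
                if vals:
                    newly.append((r, c, np.median(np.array(vals), axis=0)))
        for r, c, v in newly:
            img[r, c] = v
            todo[r, c] = False
            known[r, c] = True
    return np.clip(np.round(img), 0, 255).astype(image.dtype)


class TestMedianInpaint:
    def test_empty_mask_is_identity(self):
        cfg = HairRemovalConfig()
        img = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        out = median_inpaint(img, np.zeros((4, 4), dtype=bool), cfg)
        assert np.array_equal(out, img)

    def test_constant_neighbourhood(self):
        cfg = HairRemovalConfig(inpaint_window=3)
        img = np.full((5, 5, 3), 100, dtype=np.uint8)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert np.array_equal(median_inpaint(img, mask, cfg),
                              np.full((5, 5, 3), 100))

    def test_even_donor_count_midpoint_median(self):
        # 8 donors {10..80}: midpoint median (40+50)/2 = 45
        cfg = HairRemovalConfig(inpaint_window=3)
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        vals = [10, 20, 30, 40, 50, 60, 70, 80]
        k = 0
        for r in range(3):
            for c in range(3):
                if (r, c) != (1, 1):
                    img[r, c] = vals[k]
                    k += 1
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        out = median_inpaint(img, mask, cfg)
        assert np.all(out[1, 1] == 45)

    def test_full_mask_rejected(self):
        cfg = HairRemovalConfig()
        with pytest.raises(ValueError, match="entire image"):
            median_inpaint(np.zeros((4, 4, 3), dtype=np.uint8),
                           np.ones((4, 4), dtype=bool), cfg)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_brute_force_oracle(self, rng, window):
        cfg = HairRemovalConfig(inpaint_window=window)
        for _ in range(3):
            img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
            mask = rng.random((16, 16)) < 0.25
            mask[0, :] = False  # guarantee donors
            out = median_inpaint(img, mask, cfg)
            assert np.array_equal(out, inpaint_oracle(img, mask, window))
            assert np.array_equal(out[~mask], img[~mask])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            HairRemovalConfig(inpaint_window=4)


class TestRemoveHair:
    def test_hairless_image_near_idempotent(self):
        s = generate_sample(SynthParams(seed=3))
        out, mask = remove_hair(s.image, seed=0)
        assert mask.sum() < 0.005 * mask.size
        assert np.array_equal(out[~mask], s.image[~mask])

    def test_synthetic_strokes_recovered(self, hairy_sample):
        out, mask = remove_hair(hairy_sample.image, seed=0)
        gt = hairy_sample.hair_mask
        recall = (mask & gt).sum() / gt.sum()
        assert recall >= 0.6
        # untouched outside the mask, bit-identical
        assert np.array_equal(out[~mask], hairy_sample.image[~mask])

    def test_inpainted_values_within_surrounding_range(self, hairy_sample):
        out, mask = remove_hair(hairy_sample.image, seed=0)
        if mask.any():
            lo, hi = out[~mask].min(), out[~mask].max()
            assert out[mask].min() >= lo and out[mask].max() <= hi

    def test_seeded_runs_identical(self, hairy_sample):
        out1, m1 = remove_hair(hairy_sample.image, seed=4)
        out2, m2 = remove_hair(hairy_sample.image, seed=4)
        assert np.array_equal(out1, out2) and np.array_equal(m1, m2)


def test_transformer_wraps_functional_path(hairy_sample):
    est = HairRemover()
    cleaned = est.fit().transform([hairy_sample.image])
    ref, mask = remove_hair(hairy_sample.image, HairRemovalConfig(), seed=0)
    assert np.array_equal(cleaned[0], ref)
    assert np.array_equal(est.masks_[0], mask)
    assert "canny_low" in est.get_params()
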