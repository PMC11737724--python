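"""Morphology-Hough hair removal for dermoscopic images.

Dark hair strands occlude lesion boundaries and corrupt downstream
segmentation.  The removal proceeds in six steps: grayscale conversion,
Canny edge detection with very-bright pixels excluded (specular highlights
are never hair), morphological closing then erosion to bridge gaps and drop
isolated noise, a probabilistic Hough line transform to recover straight
strand candidates with implausibly short or long lines discarded, dilation
of the rasterised line mask to cover the full strand width, and median
inpainting of the masked pixels from their unmasked neighbourhood.

Coordinates are (row, col), 0-based.  Non-masked pixels are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as draw_line
from skimage.feature import canny
from skimage.morphology import closing, dilation, disk, erosion
from skimage.transform import probabilistic_hough_line
from sklearn.base import BaseEstimator, TransformerMixin

# Rec. 601 luma weights; any fixed convex weighting would serve.
_LUMA = np.array([0.299, 0.587, 0.114])

_HOUGH_LINE_GAP = 6  # px tolerance for broken strands


@dataclass
class LineSegment:
    """One detected hair candidate, endpoints in (row, col) pixel coords."""

    p0: tuple[int, int]
    p1: tuple[int, int]

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))


@dataclass
class HairRemovalConfig:
    """All tunables of the hair-removal stage.

    The procedure fixes the steps but not their thresholds; these defaults
    are engineering choices exposed for per-dataset tuning.
    """

    canny_low: float = 30.0       # gradient thresholds on the 0-255 scale
    canny_high: float = 90.0
    canny_sigma: float = 1.0
    bright_cutoff: float = 200.0  # gray level above which pixels are excluded
    close_radius: int = 2         # disk radius for morphological closing
    erode_radius: int = 1         # disk radius for erosion
    hough_threshold: int = 8      # minimum accumulator votes
    min_line_len: int = 10        # px; shorter candidates discarded
    max_line_len: int | None = None  # px; None -> 0.9 * max(H, W)
    dilate_radius: int = 2        # "slightly expand" the rasterised mask
    inpaint_window: int = 5       # odd neighbourhood side for the median

    def __post_init__(self) -> None:
        if not 0 < self.canny_low < self.canny_high:
            raise ValueError("need 0 < canny_low < canny_high")
        if self.close_radius < 0 or self.erode_radius < 0 or self.dilate_radius < 0:
            raise ValueError("structuring-element radii must be non-negative")
        if self.max_line_len is not None and self.min_line_len >= self.max_line_len:
            raise ValueError("min_line_len must be < max_line_len")
        if self.inpaint_window < 3 or self.inpaint_window % 2 == 0:
            raise ValueError("inpaint_window must be odd and >= 3")

    def resolved_max_len(self, shape: tuple[int, int]) -> float:
        if self.max_line_len is not None:
            return float(self.max_line_len)
        return 0.9 * max(shape)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an H x W x 3 8-bit image, rounded to uint8."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    return np.clip(np.round(image.astype(np.float64) @ _LUMA), 0, 255).astype(np.uint8)


def detect_hair_edges(gray: np.ndarray, cfg: HairRemovalConfig) -> np.ndarray:
    """Canny edge map with very bright pixels suppressed."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("detect_hair_edges expects a 2-D grayscale grid")
    edges = canny(
        gray.astype(np.float64) / 255.0,
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low / 255.0,
        high_threshold=cfg.canny_high / 255.0,
    )
    edges[gray > cfg.bright_cutoff] = False
    return edges


def refine_edge_map(edges: np.ndarray, cfg: HairRemovalConfig) -> np.ndarray:
    """Morphological closing (bridge gaps) then erosion (drop isolated noise)."""
    refined = np.asarray(edges, dtype=bool)
    if cfg.close_radius > 0:
        refined = closing(refined, disk(cfg.close_radius))
    if cfg.erode_radius > 0:
        refined = erosion(refined, disk(cfg.erode_radius))
    return refined


def extract_hair_lines(refined: np.ndarray, cfg: HairRemovalConfig,
                       seed: int = 0) -> list[LineSegment]:
    """Probabilistic Hough line candidates, length-filtered.

    The transform samples edge points at random, hence the explicit seed.
    """
    refined = np.asarray(refined, dtype=bool)
    max_len = cfg.resolved_max_len(refined.shape)
    raw = probabilistic_hough_line(
        refined,
        threshold=cfg.hough_threshold,
        line_length=cfg.min_line_len,
        line_gap=_HOUGH_LINE_GAP,
        rng=seed,
    )
    H, W = refined.shape
    lines: list[LineSegment] = []
    for (x0, y0), (x1, y1) in raw:  # skimage returns (col, row) pairs
        seg = LineSegment(
            p0=(int(np.clip(y0, 0, H - 1)), int(np.clip(x0, 0, W - 1))),
            p1=(int(np.clip(y1, 0, H - 1)), int(np.clip(x1, 0, W - 1))),
        )
        if cfg.min_line_len <= seg.length <= max_len:
            lines.append(seg)
    return lines


def rasterize_hair_mask(lines: list[LineSegment], shape: tuple[int, int],
                        cfg: HairRemovalConfig) -> np.ndarray:
    """Union of 1-px rasterised lines, dilated by a disk of dilate_radius."""
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    for seg in lines:
        for r, c in (seg.p0, seg.p1):
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(f"line endpoint {(r, c)} outside frame {shape}")
        rr, cc = draw_line(seg.p0[0], seg.p0[1], seg.p1[0], seg.p1[1])
        mask[rr, cc] = True
    if cfg.dilate_radius > 0 and mask.any():
        mask = dilation(mask, disk(cfg.dilate_radius))
    return mask


def median_inpaint(image: np.ndarray, mask: np.ndarray,
                   cfg: HairRemovalConfig) -> np.ndarray:
    """Replace masked pixels by the per-channel median of unmasked neighbours.

    Fills boundary-inward: each pass fills every masked pixel that has at
    least one unmasked (or previously filled) neighbour inside its
    inpaint_window, using donors known at the start of the pass.  The median
    of an even donor count is the usual midpoint (average of the two central
    order statistics).
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image shapes differ")
    if mask.all():
        raise ValueError("mask covers the entire image; no donor pixels")
    if not mask.any():
        return image.copy()

    work = image.astype(np.float64).copy()
    remaining = mask.copy()
    known = ~mask
    half = cfg.inpaint_window // 2
    H, W = mask.shape
    while remaining.any():
        fills: list[tuple[int, int, np.ndarray]] = []
        for r, c in np.argwhere(remaining):
            r0, r1 = max(r - half, 0), min(r + half + 1, H)
            c0, c1 = max(c - half, 0), min(c + half + 1, W)
            donors = known[r0:r1, c0:c1]
            if not donors.any():
                continue
            fills.append((r, c, np.median(work[r0:r1, c0:c1][donors], axis=0)))
        for r, c, v in fills:
            work[r, c] = v
            remaining[r, c] = False
            known[r, c] = True
    return np.clip(np.round(work), 0, 255).astype(image.dtype)


def remove_hair(image: np.ndarray, cfg: HairRemovalConfig | None = None,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Full hair-removal pass: returns (inpainted image, final hair mask)."""
    cfg = cfg or HairRemovalConfig()
    gray = to_grayscale(image)
    edges = detect_hair_edges(gray, cfg)
    refined = refine_edge_map(edges, cfg)
    lines = extract_hair_lines(refined, cfg, seed=seed)
    mask = rasterize_hair_mask(lines, gray.shape, cfg)
    if mask.any():
        cleaned = median_inpaint(image, mask, cfg)
    else:
        cleaned = image.copy()
    return cleaned, mask


class HairRemover(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping the morphology-Hough hair removal.

    `transform` maps a list (or array) of H x W x 3 uint8 images to their
    inpainted versions; the hair masks of the last call are kept in
    `masks_`.  Parameters mirror :class:`HairRemovalConfig`.
    """

    def __init__(self, canny_low: float = 30.0, canny_high: float = 90.0,
                 canny_sigma: float = 1.0, bright_cutoff: float = 200.0,
                 close_radius: int = 2, erode_radius: int = 1,
                 hough_threshold: int = 8, min_line_len: int = 10,
                 max_line_len: int | None = None, dilate_radius: int = 2,
                 inpaint_window: int = 5, seed: int = 0):
        self.canny_low = canny_low
        self.canny_high = canny_high
        self.canny_sigma = canny_sigma
        self.bright_cutoff = bright_cutoff
        self.close_radius = close_radius
        self.erode_radius = erode_radius
        self.hough_threshold = hough_threshold
        self.min_line_len = min_line_len
        self.max_line_len = max_line_len
        self.dilate_radius = dilate_radius
        self.inpaint_window = inpaint_window
        self.seed = seed

    def _config(self) -> HairRemovalConfig:
        return HairRemovalConfig(
            canny_low=self.canny_low, canny_high=self.canny_high,
            canny_sigma=self.canny_sigma, bright_cutoff=self.bright_cutoff,
            close_radius=self.close_radius, erode_radius=self.erode_radius,
            hough_threshold=self.hough_threshold, min_line_len=self.min_line_len,
            max_line_len=self.max_line_len, dilate_radius=self.dilate_radius,
            inpaint_window=self.inpaint_window,
        )

    def fit(self, X=None, y=None) -> "HairRemover":
        return self

    def transform(self, X) -> list[np.ndarray]:
        cfg = self._config()
        cleaned, masks = [], []
        for img in X:
            out, mask = remove_hair(np.asarray(img), cfg, seed=self.seed)
            cleaned.append(out)
            masks.append(mask)
        self.masks_ = masks
        return cleaned
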