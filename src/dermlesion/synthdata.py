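"""Seeded generator of dermoscopy-like images with exact ground truth.

Each sample is a skin-tone background with a smooth illumination ramp, one
darker lesion whose outline is a radially perturbed ellipse (controlled by
border-irregularity, asymmetry and colour-variegation parameters), and
optional dark near-linear hair strokes.  The lesion mask, hair mask and the
benign/malignant label are known exactly by construction, which gives the
hair-removal, segmentation and classification stages a download-free,
fully verifiable test surface.

The label is a deterministic function of the morphology parameters:
malignant iff border_irregularity > 0.4 or color_variegation >= 3 or
asymmetry > 0.3 (thresholds fixed; recorded in each sample's provenance).
Clinically this mimics the ABC criteria — asymmetry, border irregularity,
colour variegation — that dermatologists use for melanoma triage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk

from .metrics import BENIGN, MALIGNANT

LABEL_THRESHOLDS = {
    "border_irregularity": 0.4,
    "color_variegation": 3,
    "asymmetry": 0.3,
}


@dataclass
class LesionSpec:
    """Geometry and appearance of the single lesion."""

    center: tuple[float, float] | None = None  # (row, col); None -> frame centre
    axes: tuple[float, float] = (18.0, 13.0)   # semi-axes in pixels
    rotation: float = 0.0                      # radians
    darkening: float = 0.45                    # contrast vs local background
    border_irregularity: float = 0.0           # radial-noise amplitude, 0..1
    asymmetry: float = 0.0                     # axis-skew factor, 0..1
    color_variegation: int = 0                 # number of darker sub-blobs


@dataclass
class HairSpec:
    count: int = 0
    thickness: int = 2                 # stroke width in pixels
    length_range: tuple[int, int] = (30, 60)
    intensity: float = 35.0            # dark gray level of strokes


@dataclass
class SynthParams:
    size: tuple[int, int] = (64, 64)
    skin_tone: tuple[float, float, float] = (196.0, 150.0, 125.0)
    illumination_gradient: float = 18.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    hairs: HairSpec = field(default_factory=HairSpec)
    noise_sd: float = 4.0
    seed: int = 0


@dataclass
class SynthSample:
    image: np.ndarray          # H x W x 3 uint8
    lesion_mask: np.ndarray    # H x W bool
    hair_mask: np.ndarray      # H x W bool
    label: str                 # benign | malignant
    image_id: str = ""
    provenance: dict = field(default_factory=dict)


def label_from_lesion(lesion: LesionSpec) -> str:
    t = LABEL_THRESHOLDS
    malignant = (
        lesion.border_irregularity > t["border_irregularity"]
        or lesion.color_variegation >= t["color_variegation"]
        or lesion.asymmetry > t["asymmetry"]
    )
    return MALIGNANT if malignant else BENIGN


def _lesion_outline(lesion: LesionSpec, center: tuple[float, float],
                    rng: np.random.Generator, n_vertices: int = 720):
    """Polygon vertices (rows, cols) of the radially perturbed ellipse."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = lesion.axes
    tt = theta - lesion.rotation
    r = a * b / np.sqrt((b * np.cos(tt)) ** 2 + (a * np.sin(tt)) ** 2)
    if lesion.border_irregularity > 0:
        # smooth periodic noise: random-phase harmonics, normalised to [-1, 1]
        s = np.zeros_like(theta)
        for h in range(3, 9):
            s += rng.normal() * np.cos(h * theta) + rng.normal() * np.sin(h * theta)
        s /= np.abs(s).max() + 1e-9
        r = r * (1.0 + 0.35 * lesion.border_irregularity * s)
    if lesion.asymmetry > 0:
        r = r * (1.0 + lesion.asymmetry * np.cos(tt))
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return rows, cols


def _draw_hairs(shape: tuple[int, int], hairs: HairSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Union mask of slightly curved polyline strokes (<= 3 control points)."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(hairs.count):
        length = rng.integers(hairs.length_range[0], hairs.length_range[1] + 1)
        ang = rng.uniform(0.0, np.pi)
        d = np.array([np.sin(ang), np.cos(ang)])
        p0 = rng.uniform([2, 2], [H - 3, W - 3])
        p2 = p0 + d * length
        perp = np.array([-d[1], d[0]])
        p1 = (p0 + p2) / 2 + perp * rng.uniform(-0.06, 0.06) * length
        t = np.linspace(0.0, 1.0, 4 * int(length))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        rr = np.round(pts[:, 0]).astype(int)
        cc = np.round(pts[:, 1]).astype(int)
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)  # hairs may exit frame
        mask[rr[keep], cc[keep]] = True
    if hairs.thickness > 1:
        mask = dilation(mask, disk(hairs.thickness // 2))
    return mask


def generate_sample(params: SynthParams) -> SynthSample:
    """Render one seeded synthetic dermoscopic image with ground truth."""
    H, W = params.size
    rng = np.random.default_rng(params.seed)
    lesion = params.lesion
    center = lesion.center if lesion.center is not None else (H / 2.0, W / 2.0)

    rows, cols = _lesion_outline(lesion, center, rng)
    margin = 1.0
    if (rows.min() < margin or cols.min() < margin
            or rows.max() > H - 1 - margin or cols.max() > W - 1 - margin):
        raise ValueError("lesion outline does not fit inside the image frame")
    lesion_mask = np.zeros((H, W), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=(H, W))
    lesion_mask[rr, cc] = True

    # background: skin tone + smooth illumination plane
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(params.skin_tone)
    gdir = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:H, 0:W]
    ramp = ((yy / max(H - 1, 1) - 0.5) * np.sin(gdir)
            + (xx / max(W - 1, 1) - 0.5) * np.cos(gdir))
    img += params.illumination_gradient * ramp[:, :, None]

    # lesion: multiplicative darkening keeps every lesion pixel strictly
    # darker than the local (pre-noise) background
    img[lesion_mask] *= 1.0 - lesion.darkening

    # colour variegation: darker sub-blobs inside the lesion
    for _ in range(lesion.color_variegation):
        for _attempt in range(100):
            r0 = rng.uniform(0, H)
            c0 = rng.uniform(0, W)
            if lesion_mask[int(r0), int(c0)]:
                break
        radius = rng.uniform(0.1, 0.22) * min(lesion.axes)
        rr, cc = draw_disk((r0, c0), max(radius, 1.0), shape=(H, W))
        keep = lesion_mask[rr, cc]
        shade = rng.uniform(0.45, 0.75)
        tint = np.array([shade, shade * rng.uniform(0.8, 1.0),
                         shade * rng.uniform(0.7, 1.0)])
        img[rr[keep], cc[keep]] *= tint

    hair_mask = _draw_hairs((H, W), params.hairs, rng)
    if hair_mask.any():
        img[hair_mask] = params.hairs.intensity + rng.normal(
            0.0, 2.0, size=(int(hair_mask.sum()), 3))

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return SynthSample(
        image=image,
        lesion_mask=lesion_mask,
        hair_mask=hair_mask,
        label=label_from_lesion(lesion),
        provenance={
            "params": dataclasses.asdict(params),
            "label_thresholds": dict(LABEL_THRESHOLDS),
        },
    )


def _draw_lesion_spec(rng: np.random.Generator, malignant: bool,
                      size: tuple[int, int], template: SynthParams) -> LesionSpec:
    H, W = size
    base = min(H, W)
    a = rng.uniform(0.16, 0.24) * base
    b = a * rng.uniform(0.6, 0.95)
    center = (H / 2 + rng.uniform(-0.05, 0.05) * H,
              W / 2 + rng.uniform(-0.05, 0.05) * W)
    if malignant:
        irregularity = rng.uniform(0.55, 0.85)
        asymmetry = rng.uniform(0.35, 0.55)
        variegation = int(rng.integers(3, 6))
    else:
        irregularity = rng.uniform(0.0, 0.25)
        asymmetry = rng.uniform(0.0, 0.15)
        variegation = int(rng.integers(0, 2))
    return LesionSpec(
        center=center,
        axes=(a, b),
        rotation=rng.uniform(0.0, np.pi),
        darkening=template.lesion.darkening,
        border_irregularity=irregularity,
        asymmetry=asymmetry,
        color_variegation=variegation,
    )


def generate_dataset(n: int, malignant_fraction: float = 0.5,
                     template: SynthParams | None = None, seed: int = 0,
                     out_dir: str | Path | None = None) -> list[SynthSample]:
    """Generate `n` seeded samples; optionally write the on-disk layout.

    Label counts follow round(n * malignant_fraction).  With `out_dir` set,
    writes `images/`, `masks/`, `hair_masks/` PNG trees plus `metadata.csv`
    — exactly the layout the training commands consume.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= malignant_fraction <= 1.0:
        raise ValueError("malignant_fraction must lie in [0, 1]")
    template = template or SynthParams()
    master = np.random.default_rng(seed)
    n_mal = int(round(n * malignant_fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:n_mal] = True
    master.shuffle(flags)

    samples: list[SynthSample] = []
    for i, malignant in enumerate(flags):
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(sub_seed)
        lesion = _draw_lesion_spec(rng, bool(malignant), template.size, template)
        params = dataclasses.replace(
            template, lesion=lesion,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        sample = generate_sample(params)
        sample.image_id = f"synth_{i:04d}"
        samples.append(sample)

    if out_dir is not None:
        write_dataset(samples, out_dir)
    return samples


def write_dataset(samples: list[SynthSample], out_dir: str | Path) -> Path:
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    for sub in ("images", "masks", "hair_masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        iio.imwrite(out / "images" / f"{s.image_id}.png", s.image)
        iio.imwrite(out / "masks" / f"{s.image_id}.png",
                    (s.lesion_mask * 255).astype(np.uint8))
        iio.imwrite(out / "hair_masks" / f"{s.image_id}.png",
                    (s.hair_mask * 255).astype(np.uint8))
        rows.append({"image_id": s.image_id, "label": s.label})
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    return out
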