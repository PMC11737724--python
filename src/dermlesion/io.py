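"""Dataset and image I/O.

On-disk layout (what the synthetic generator writes and the training
commands read)::

    dataset/
      images/<image_id>.png        # RGB dermoscopic image (PNG or JPEG)
      masks/<image_id>.png         # optional lesion masks, single channel 0/255
      hair_masks/<image_id>.png    # optional hair masks
      metadata.csv                 # image_id,label  (benign/malignant or a
                                   #  diagnosis code run through the mapping)

Images are paired to masks by filename stem; all pairing problems are
reported together in one aggregated error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classification import map_diagnosis

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class DatasetRecord:
    image_id: str
    image: np.ndarray
    mask: np.ndarray | None = None
    hair_mask: np.ndarray | None = None
    label: str | None = None


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image; grayscale is expanded to 3 channels."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr.astype(np.uint8)


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def save_image(path: str | Path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def _stems(folder: Path) -> dict[str, Path]:
    if not folder.is_dir():
        return {}
    return {p.stem: p for p in sorted(folder.iterdir())
            if p.suffix.lower() in _IMAGE_EXTS}


def load_dataset(root: str | Path, require_masks: bool = False,
                 require_labels: bool = False) -> list[DatasetRecord]:
    """Load a dataset directory into paired records.

    Pairing mismatches (orphan masks, missing labels, unreadable files) are
    collected and raised together in a single error naming each stem.
    """
    root = Path(root)
    images = _stems(root / "images")
    if not images:
        raise FileNotFoundError(f"no images found under {root / 'images'}")
    masks = _stems(root / "masks")
    hair_masks = _stems(root / "hair_masks")

    labels: dict[str, str] = {}
    meta_path = root / "metadata.csv"
    problems: list[str] = []
    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype=str)
        for _, row in meta.iterrows():
            try:
                labels[row["image_id"]] = map_diagnosis(row["label"])
            except ValueError as e:
                problems.append(str(e))

    for stem in masks:
        if stem not in images:
            problems.append(f"orphan mask without image: {stem}")
    for stem in labels:
        if stem not in images:
            problems.append(f"metadata row without image: {stem}")

    records: list[DatasetRecord] = []
    for stem, path in images.items():
        try:
            image = load_image(path)
        except Exception as e:  # noqa: BLE001 - aggregate and report
            problems.append(f"unreadable image {stem}: {e}")
            continue
        mask = load_mask(masks[stem]) if stem in masks else None
        hair = load_mask(hair_masks[stem]) if stem in hair_masks else None
        label = labels.get(stem)
        if require_masks and mask is None:
            problems.append(f"missing mask for image: {stem}")
        if require_labels and label is None:
            problems.append(f"missing label for image: {stem}")
        records.append(DatasetRecord(image_id=stem, image=image, mask=mask,
                                     hair_mask=hair, label=label))
    if problems:
        raise ValueError("dataset problems:\n  " + "\n  ".join(sorted(problems)))
    return records
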