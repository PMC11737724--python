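"""End-to-end orchestration: preprocess -> segment -> crop -> classify -> evaluate.

The stage order is fixed: hair removal runs once at ingest, the segmenter
predicts a lesion mask on the cleaned image, the lesion crop (tight
bounding box of the mask padded by 10%, background outside the mask zeroed)
is resized to the classifier's grayscale patch size, and the random forest
emits the benign/malignant call.  Every stage seed derives deterministically
from one global seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .classification import AlexNetRFClassifier
from .hair_removal import HairRemovalConfig, remove_hair
from .io import DatasetRecord, load_dataset
from .metrics import (
    classification_metrics,
    confusion_counts,
    dice,
    jaccard,
)
from .segmentation import ResUNetSegmenter

log = logging.getLogger("dermlesion")

CROP_PAD_FRACTION = 0.1


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from one global seed."""
    rng = np.random.default_rng(global_seed)
    return {name: int(rng.integers(2 ** 31 - 1))
            for name in ("synth", "hair", "segmenter", "classifier")}


@dataclass
class PipelineConfig:
    """One structured config covering every stage; YAML-serialisable."""

    hair_removal: dict[str, Any] = field(default_factory=dict)
    hair_removal_enabled: bool = True
    segmenter: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)
    global_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.hair_config()  # raises on invalid values
        seeds = derive_seeds(self.global_seed)
        ResUNetSegmenter(**{"seed": seeds["segmenter"], **self.segmenter})._spec()
        AlexNetRFClassifier(**{"seed": seeds["classifier"], **self.classifier})._spec()

    def hair_config(self) -> HairRemovalConfig:
        return HairRemovalConfig(**self.hair_removal)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def lesion_crop(image: np.ndarray, mask: np.ndarray,
                pad_fraction: float = CROP_PAD_FRACTION) -> np.ndarray:
    """Tight bounding box of the mask padded by 10%, background zeroed.

    Falls back to the full (unmasked) image when the mask is empty, so a
    failed segmentation degrades gracefully rather than erroring.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return image.copy()
    zeroed = image * mask[:, :, None] if image.ndim == 3 else image * mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    pr = int(round((r1 - r0) * pad_fraction))
    pc = int(round((c1 - c0) * pad_fraction))
    r0, r1 = max(r0 - pr, 0), min(r1 + pr, mask.shape[0])
    c0, c1 = max(c0 - pc, 0), min(c1 + pc, mask.shape[1])
    return zeroed[r0:r1, c0:c1]


def run_pipeline(image: np.ndarray, segmenter: ResUNetSegmenter,
                 classifier: AlexNetRFClassifier,
                 hair_cfg: HairRemovalConfig | None = None,
                 hair_removal_enabled: bool = True,
                 seed: int = 0) -> dict[str, Any]:
    """Run one image through all three stages; returns every intermediate."""
    if hair_removal_enabled:
        cleaned, hair_mask = remove_hair(image, hair_cfg, seed=seed)
    else:  # documented identity behaviour, never a silent skip
        cleaned = np.asarray(image).copy()
        hair_mask = np.zeros(np.asarray(image).shape[:2], dtype=bool)
    log.info("stage=hair_removal masked_px=%d", int(hair_mask.sum()))
    mask = segmenter.predict_mask(cleaned)
    log.info("stage=segmentation lesion_px=%d", int(mask.sum()))
    crop = lesion_crop(cleaned, mask)
    label, prob = classifier.classify(crop)
    log.info("stage=classification label=%s p=%.3f", label, prob)
    return {
        "cleaned": cleaned,
        "hair_mask": hair_mask,
        "lesion_mask": mask,
        "crop": crop,
        "label": label,
        "probability": prob,
    }


def evaluate_run(records: list[DatasetRecord], segmenter: ResUNetSegmenter,
                 classifier: AlexNetRFClassifier | None = None,
                 hair_cfg: HairRemovalConfig | None = None,
                 hair_removal_enabled: bool = True,
                 mask_source: str = "predicted", seed: int = 0) -> dict[str, Any]:
    """Per-image Dice/Jaccard plus aggregate confusion metrics over a dataset.

    ``mask_source`` chooses whether classifier inputs come from predicted
    masks or the ground-truth masks.
    """
    if not records:
        raise ValueError("empty dataset")
    if mask_source not in ("predicted", "truth"):
        raise ValueError("mask_source must be 'predicted' or 'truth'")
    per_image = []
    pred_labels, true_labels = [], []
    for rec in records:
        if hair_removal_enabled:
            cleaned, _ = remove_hair(rec.image, hair_cfg, seed=seed)
        else:
            cleaned = rec.image
        pred_mask = segmenter.predict_mask(cleaned)
        row: dict[str, Any] = {"image_id": rec.image_id}
        if rec.mask is not None:
            row["dice"] = dice(rec.mask, pred_mask)
            row["jaccard"] = jaccard(rec.mask, pred_mask)
        if classifier is not None and rec.label is not None:
            use_mask = rec.mask if (mask_source == "truth"
                                    and rec.mask is not None) else pred_mask
            label, prob = classifier.classify(lesion_crop(cleaned, use_mask))
            row["label_true"] = rec.label
            row["label_pred"] = label
            row["probability"] = prob
            pred_labels.append(label)
            true_labels.append(rec.label)
        per_image.append(row)

    report: dict[str, Any] = {"per_image": per_image, "n": len(records)}
    dices = [r["dice"] for r in per_image if "dice" in r]
    if dices:
        report["mean_dice"] = float(np.mean(dices))
        report["mean_jaccard"] = float(
            np.mean([r["jaccard"] for r in per_image if "jaccard" in r]))
    if pred_labels:
        counts = confusion_counts(pred_labels, true_labels)
        m = classification_metrics(counts)
        report["confusion"] = {"tp": counts.tp, "tn": counts.tn,
                               "fp": counts.fp, "fn": counts.fn}
        report["accuracy"] = m.accuracy
        report["sensitivity"] = m.sensitivity
        report["specificity"] = m.specificity
    return report


def evaluate_directory(data_dir: str | Path, segmenter: ResUNetSegmenter,
                       classifier: AlexNetRFClassifier | None = None,
                       **kwargs) -> dict[str, Any]:
    records = load_dataset(data_dir, require_masks=True)
    return evaluate_run(records, segmenter, classifier, **kwargs)
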