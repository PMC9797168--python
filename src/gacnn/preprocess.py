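"""Fundus image preprocessing: crop, resize, enhance, class balancing.

The pipeline mirrors the standard preparation of retinal photographs for
grading networks: (1) remove the black frame by cropping a square whose
side is the fundus diameter, centred on the fundus centre; (2) resize to
the network input side (224 by default); (3) enhance with optional
brightness/colour/contrast factors followed by a Gaussian-blur difference
blend (w1*I + w2*blur(I) + bias), which flattens illumination and makes
small lesions pop; (4) balance the class distribution to a fixed count per
class by subsampling surplus classes and topping up deficit classes with
seeded flip/rotation/shift variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageEnhance
from scipy import ndimage

from .synthetic import LabeledImageSet

__all__ = ["PreprocessConfig", "DegenerateImageError", "crop_fundus",
           "enhance", "resize", "augment_balance", "preprocess_image"]


class DegenerateImageError(ValueError):
    """Raised when an image contains no detectable fundus disc."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_side: int = 224
    border_threshold: float = 10.0
    blur_sigma: float = 7.0
    blend_weights: tuple[float, float] = (4.0, -4.0)
    blend_bias: float = 128.0
    brightness: float = 1.0
    color: float = 1.0
    contrast: float = 1.0
    balance_target: int = 1800
    augmentations: frozenset = frozenset({"flip", "rotation", "shift"})
    max_shift_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.target_side <= 0:
            raise ValueError("target_side must be positive")
        if self.balance_target < 1:
            raise ValueError("balance_target must be >= 1")
        if not np.all(np.isfinite(self.blend_weights)):
            raise ValueError("blend weights must be finite")


def crop_fundus(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Square-crop the fundus: side = disc diameter, centre = disc centre.

    Pixels darker than ``cfg.border_threshold`` (grayscale) count as
    background frame. The crop is padded with black where the square
    extends past the image bounds, so the disc always stays centred.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a nonempty HxWx3 RGB array")
    gray = image.astype(np.float64).mean(axis=2)
    mask = gray > cfg.border_threshold
    if not mask.any():
        raise DegenerateImageError("no pixels above the border threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    height = rows[-1] - rows[0] + 1
    width = cols[-1] - cols[0] + 1
    diameter = int(max(height, width))
    cy = (rows[0] + rows[-1]) / 2.0
    cx = (cols[0] + cols[-1]) / 2.0
    y0 = int(round(cy - diameter / 2.0))
    x0 = int(round(cx - diameter / 2.0))
    out = np.zeros((diameter, diameter, 3), dtype=image.dtype)
    src_y0, src_y1 = max(0, y0), min(image.shape[0], y0 + diameter)
    src_x0, src_x1 = max(0, x0), min(image.shape[1], x0 + diameter)
    out[src_y0 - y0:src_y1 - y0, src_x0 - x0:src_x1 - x0] = \
        image[src_y0:src_y1, src_x0:src_x1]
    return out


def resize(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Resize to ``target_side`` x ``target_side`` (bilinear; identity if already there)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    side = cfg.target_side
    if image.shape[0] == side and image.shape[1] == side:
        return image.copy()
    pil = Image.fromarray(image).resize((side, side), Image.BILINEAR)
    return np.asarray(pil)


def enhance(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Brightness/colour/contrast adjustment + Gaussian-blur difference blend.

    output = clip(w1*I' + w2*gaussian_blur(I', sigma) + bias) where I' is
    the factor-adjusted image. With the default weights (4, -4) and bias
    128 this is the familiar fundus high-pass enhancement; a constant
    image maps to the constant ``bias``.
    """
    if cfg.blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    image = np.asarray(image)
    pil = Image.fromarray(image.astype(np.uint8))
    if cfg.brightness != 1.0:
        pil = ImageEnhance.Brightness(pil).enhance(cfg.brightness)
    if cfg.color != 1.0:
        pil = ImageEnhance.Color(pil).enhance(cfg.color)
    if cfg.contrast != 1.0:
        pil = ImageEnhance.Contrast(pil).enhance(cfg.contrast)
    arr = np.asarray(pil).astype(np.float64)
    blurred = np.empty_like(arr)
    for ch in range(arr.shape[2]):
        blurred[..., ch] = ndimage.gaussian_filter(arr[..., ch], cfg.blur_sigma)
    w1, w2 = cfg.blend_weights
    out = w1 * arr + w2 * blurred + cfg.blend_bias
    return np.clip(out, 0, 255).astype(image.dtype)


def preprocess_image(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """crop -> resize -> enhance, the full single-image pipeline."""
    return enhance(resize(crop_fundus(image, cfg), cfg), cfg)


def _augment_one(image: np.ndarray, rng: np.random.Generator,
                 cfg: PreprocessConfig) -> np.ndarray:
    pil = Image.fromarray(image)
    ops = cfg.augmentations
    if "flip" in ops and rng.random() < 0.5:
        pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
    if "rotation" in ops:
        angle = rng.uniform(-180.0, 180.0)
        pil = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    if "shift" in ops:
        h, w = image.shape[:2]
        dx = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * w
        dy = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * h
        pil = pil.transform(pil.size, Image.AFFINE, (1, 0, -dx, 0, 1, -dy),
                            resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    return np.asarray(pil)


def augment_balance(dataset: LabeledImageSet,
                    cfg: PreprocessConfig = PreprocessConfig()) -> LabeledImageSet:
    """Equalise the class histogram at ``cfg.balance_target`` per class.

    Surplus classes are subsampled without replacement (seeded); deficit
    classes are topped up by cycling over their originals and applying
    seeded flip/rotation/shift variants. Augmented ids derive from their
    parent id (``<parent>_aug<k>``).
    """
    target = cfg.balance_target
    by_class: dict[int, list[int]] = {}
    for i, y in enumerate(dataset.labels):
        by_class.setdefault(y, []).append(i)
    for y, idxs in by_class.items():
        if not idxs:
            raise ValueError(f"class {y} has no images")
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0xBA1)))
    images, labels, ids = [], [], []
    for y in sorted(by_class):
        idxs = by_class[y]
        if len(idxs) >= target:
            keep = rng.choice(len(idxs), size=target, replace=False)
            chosen = [idxs[k] for k in sorted(keep)]
            for i in chosen:
                images.append(dataset.images[i])
                labels.append(y)
                ids.append(dataset.ids[i])
        else:
            for i in idxs:
                images.append(dataset.images[i])
                labels.append(y)
                ids.append(dataset.ids[i])
            need = target - len(idxs)
            for k in range(need):
                parent = idxs[k % len(idxs)]
                images.append(_augment_one(dataset.images[parent], rng, cfg))
                labels.append(y)
                ids.append(f"{dataset.ids[parent]}_aug{k // len(idxs)}")
    return LabeledImageSet(images, labels, ids)
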