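"""Image preprocessing and training-time augmentation.

The preprocessing convention is the one common to Inception-style
classifiers: take the centered square of the image, keep the central
``crop_fraction`` (87.5 % by default) of that square, and resize to a fixed
side length (299 px in the reference recipe; desk-scale backends use much
smaller sides).

Augmentation applies, in order, a horizontal flip with probability 0.5, an
additive brightness shift drawn uniformly from ±0.125 on the normalized
[0, 1] intensity scale, and a saturation rescaling by a factor drawn
uniformly from [0.5, 1.5].  Saturation scaling blends each pixel with its
luminance, so grayscale images are fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError

# Rec. 601 luma weights used for the saturation blend.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessSpec:
    """Deterministic test-time preprocessing parameters.

    ``crop_fraction`` is a linear fraction in (0, 1]; ``target_size`` the
    output side length in pixels.
    """

    crop_fraction: float = 0.875
    target_size: int = 299

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise InputError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")
        if self.target_size < 8:
            raise InputError(f"target_size must be >= 8, got {self.target_size}")


@dataclass(frozen=True)
class AugmentSpec:
    """Stochastic training-time augmentation parameters."""

    horizontal_flip_probability: float = 0.5
    brightness_max_delta: float = 0.125
    saturation_max_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.horizontal_flip_probability <= 1.0:
            raise InputError("horizontal_flip_probability must be in [0, 1]")
        if self.brightness_max_delta < 0 or self.saturation_max_factor < 0:
            raise InputError("augmentation magnitudes must be >= 0")


def _center_square(image: np.ndarray, side: int) -> np.ndarray:
    h, w = image.shape[:2]
    top = (h - side) // 2
    left = (w - side) // 2
    return image[top : top + side, left : left + side]


def preprocess(image: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Center-crop and resize an RGB image.

    Takes the centered square of side ``min(height, width)``, then the
    centered sub-square of side ``round(crop_fraction × side)``, then
    resizes (bilinear) to ``target_size``.  Returns uint8 RGB.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise InputError(f"degenerate image of shape {image.shape}")
    side = min(h, w)
    square = _center_square(image, side)
    crop_side = max(1, int(round(spec.crop_fraction * side)))
    cropped = _center_square(square, crop_side)
    if cropped.dtype != np.uint8:
        cropped = np.clip(cropped, 0, 255).astype(np.uint8)
    if crop_side == spec.target_size:
        return cropped.copy()
    pil = Image.fromarray(cropped, mode="RGB")
    resized = pil.resize((spec.target_size, spec.target_size), Image.BILINEAR)
    return np.asarray(resized)


def augment(
    image: np.ndarray,
    spec: AugmentSpec = AugmentSpec(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply flip / brightness / saturation augmentation, deterministically
    for a given seed.  Accepts uint8 (returned as uint8) or float arrays on
    the [0, 1] scale (returned as float64).  Operations whose drawn
    magnitude is exactly neutral leave pixel values untouched.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_uint8 = image.dtype == np.uint8

    out = image
    if spec.horizontal_flip_probability > 0 and rng.random() < spec.horizontal_flip_probability:
        out = out[:, ::-1]

    work: np.ndarray | None = None  # float [0,1] copy, materialized lazily
    if spec.brightness_max_delta > 0:
        delta = rng.uniform(-spec.brightness_max_delta, spec.brightness_max_delta)
        work = (out.astype(np.float64) / 255.0) if is_uint8 else out.astype(np.float64)
        work = work + delta
    if spec.saturation_max_factor > 0:
        factor = rng.uniform(1.0 - spec.saturation_max_factor, 1.0 + spec.saturation_max_factor)
        if work is None:
            work = (out.astype(np.float64) / 255.0) if is_uint8 else out.astype(np.float64)
        gray = work @ _LUMA
        work = gray[..., None] + factor * (work - gray[..., None])

    if work is None:
        return out.copy()
    work = np.clip(work, 0.0, 1.0)
    if is_uint8:
        return np.round(work * 255.0).astype(np.uint8)
    return work


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an (H, W, 3) uint8 RGB array."""
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("RGB"))
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
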