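"""Image enrichment: whole-image resize, multiscale random patch extraction,
and light augmentation.  Deliberately NO stain/color normalization.

The default plan mirrors the source protocol for 2048x1536 images: 40, 20, 10
and 5 random crops of sides 224, 512, 1024 and 1536, each resized to 224,
plus one whole-image resize (76 outputs total).  Scales larger than the
source image are skipped with a warning so smaller synthetic images flow
through the same pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from skimage.transform import resize

__all__ = [
    "PatchPlan",
    "AugmentationPolicy",
    "Patch",
    "extract_patches",
    "augment",
    "standardize",
    "DEFAULT_PLAN",
]

ROTATIONS = (0, 90, 180, 270)


@dataclasses.dataclass(frozen=True)
class PatchPlan:
    entries: tuple[tuple[int, int], ...] = ((224, 40), (512, 20), (1024, 10), (1536, 5))
    include_whole_resize: bool = True
    output_side: int = 224

    def __post_init__(self) -> None:
        for side, count in self.entries:
            if side <= 0 or count <= 0:
                raise ValueError(f"patch sides and counts must be positive, got ({side},{count})")
        if self.output_side <= 0:
            raise ValueError("output_side must be positive")


DEFAULT_PLAN = PatchPlan()


@dataclasses.dataclass(frozen=True)
class AugmentationPolicy:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotations: tuple[int, ...] = ROTATIONS
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        for lo, hi in (self.brightness_range, self.contrast_range):
            if not (0 < lo <= 1.0 <= hi):
                raise ValueError("factor ranges must be positive and contain 1.0")
        if any(r not in ROTATIONS for r in self.rotations):
            raise ValueError(f"rotations must be multiples of 90 degrees, got {self.rotations}")
        if not self.rotations:
            raise ValueError("rotation set must be non-empty (use (0,) to disable)")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(horizontal_flip=False, vertical_flip=False, rotations=(0,),
                   brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0))


@dataclasses.dataclass
class Patch:
    """One extracted output: the resized pixel array plus its provenance."""

    image: np.ndarray  # (output_side, output_side, 3) floats in [0,1]
    scale: int  # source crop side; 0 means whole-image resize
    row: int  # top-left corner in the source image
    col: int


def _resize(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape[0] == side and img.shape[1] == side:
        return img.astype(np.float64, copy=False)
    out = resize(img, (side, side, 3), order=1, mode="reflect",
                 anti_aliasing=img.shape[0] > side, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def extract_patches(
    image: np.ndarray, plan: PatchPlan = DEFAULT_PLAN, seed: int = 0
) -> list[Patch]:
    """Random multiscale crops of ``image`` (H x W x 3 in [0,1]), all resized
    to ``plan.output_side``; reproducible for a fixed seed."""
    image = standardize(image)
    h, w = image.shape[:2]
    rng = np.random.default_rng(seed)
    out: list[Patch] = []
    if plan.include_whole_resize:
        out.append(Patch(image=_resize(image, plan.output_side), scale=0, row=0, col=0))
    any_applicable = plan.include_whole_resize
    for side, count in plan.entries:
        if side > h or side > w:
            warnings.warn(
                f"skipping {count} crops of side {side}: source image is {h}x{w}",
                stacklevel=2,
            )
            continue
        any_applicable = True
        rows = rng.integers(0, h - side + 1, size=count)
        cols = rng.integers(0, w - side + 1, size=count)
        for r, c in zip(rows, cols):
            crop = image[r:r + side, c:c + side]
            out.append(Patch(image=_resize(crop, plan.output_side),
                             scale=side, row=int(r), col=int(c)))
    if not any_applicable:
        raise ValueError("image smaller than every patch scale and whole resize disabled")
    return out


def augment(
    patch: np.ndarray, policy: AugmentationPolicy, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Apply a sampled flip/rotation/brightness/contrast transform.

    Input must be (H, W, 3) floats in [0,1]; the output is clipped to [0,1].
    The identity policy returns the input unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = standardize(patch)
    if policy.horizontal_flip and rng.random() < 0.5:
        x = x[:, ::-1]
    if policy.vertical_flip and rng.random() < 0.5:
        x = x[::-1]
    k = int(rng.choice(policy.rotations)) // 90
    if k:
        x = np.rot90(x, k=k, axes=(0, 1))
    bright = rng.uniform(*policy.brightness_range)
    contrast = rng.uniform(*policy.contrast_range)
    if bright != 1.0:
        x = x * bright
    if contrast != 1.0:
        mean = x.mean(axis=(0, 1), keepdims=True)
        x = (x - mean) * contrast + mean
    return np.clip(np.ascontiguousarray(x), 0.0, 1.0)


def standardize(patch: np.ndarray) -> np.ndarray:
    """Scale an RGB array to [0,1] floats.  No color/stain normalization."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) array, got shape {patch.shape}")
    if patch.dtype == np.uint8:
        return patch.astype(np.float64) / 255.0
    out = patch.astype(np.float64, copy=False)
    if out.size and (out.min() < 0.0 or out.max() > 1.0):
        raise ValueError("float input must already lie in [0,1]")
    return out
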