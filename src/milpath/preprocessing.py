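"""Tissue masking, patch extraction, normalization and augmentation.

Conventions used throughout the package: patch grids are 0-based,
row-major, half-open 256-px pixel windows tiled from the top-left origin;
residual borders narrower than one patch are discarded. Tissue is
detected automatically by Otsu-thresholding the HSV saturation channel
(stained tissue is saturated, glass background is not), morphologically
closed with a 5-px disk; expert masks can be supplied instead wherever a
mask argument is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk
from skimage.transform import resize, rotate

from .config import PreprocessConfig

__all__ = ["Patch", "tissue_mask", "extract_patches", "normalize_patch",
           "denormalize_patch", "augment", "patch_manifest"]


@dataclass
class Patch:
    pixels: np.ndarray   # (patch, patch, 3) uint8
    grid_row: int
    grid_col: int
    slide_id: str = ""
    tissue_fraction: float = 1.0


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image")
    return image


def tissue_mask(image: np.ndarray) -> np.ndarray:
    """Binary tissue mask: saturation > Otsu threshold, closed with 5-px disk."""
    image = _check_rgb(image)
    sat = rgb2hsv(image)[..., 1]
    if np.allclose(sat, sat.flat[0]):
        # constant saturation: all tissue if saturated, none if not
        return np.full(sat.shape, bool(sat.flat[0] > 0.5))
    thresh = threshold_otsu(sat)
    return closing(sat > thresh, disk(5)).astype(bool)


def extract_patches(image: np.ndarray, mask: np.ndarray,
                    cfg: PreprocessConfig | None = None) -> list[Patch]:
    """Tile on a fixed grid; keep patches whose tissue fraction clears the bar."""
    cfg = cfg or PreprocessConfig()
    image = _check_rgb(image)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask must match image size")
    p = cfg.patch_size_px
    n_rows, n_cols = image.shape[0] // p, image.shape[1] // p
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            window = np.s_[r * p:(r + 1) * p, c * p:(c + 1) * p]
            frac = float(mask[window].mean())
            if frac >= cfg.min_tissue_fraction:
                patches.append(Patch(pixels=image[window], grid_row=r,
                                     grid_col=c,
                                     tissue_fraction=frac))
    return patches


def normalize_patch(patch: np.ndarray | Patch,
                    cfg: PreprocessConfig | None = None) -> np.ndarray:
    """256→224 bilinear resize, scale to [0,1], ImageNet channel whitening.

    Returns a (3, 224, 224) float array, channels first.
    """
    cfg = cfg or PreprocessConfig()
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    pixels = _check_rgb(pixels)
    m = cfg.model_input_px
    x = resize(pixels.astype(np.float64) / 255.0, (m, m, 3), order=1,
               anti_aliasing=False)
    mean = np.asarray(cfg.norm_mean)
    std = np.asarray(cfg.norm_std)
    return np.moveaxis((x - mean) / std, -1, 0)


def denormalize_patch(tensor: np.ndarray,
                      cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Inverse of the whitening step (resize is not inverted)."""
    cfg = cfg or PreprocessConfig()
    mean = np.asarray(cfg.norm_mean)
    std = np.asarray(cfg.norm_std)
    x = np.moveaxis(tensor, 0, -1) * std + mean
    return np.clip(x * 255.0, 0, 255)


def augment(patch: np.ndarray | Patch, cfg: PreprocessConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation, applied in a fixed order.

    Independent 0.5-probability horizontal/vertical flips, rotation uniform
    in ±rotation_deg with reflect padding, isotropic scaling in
    ``scale_range``, then a random crop to ``model_input_px``. Output is
    uint8 RGB of size model_input_px.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    pixels = _check_rgb(pixels).astype(np.float64) / 255.0
    if cfg.flip_h and rng.random() < 0.5:
        pixels = pixels[:, ::-1]
    if cfg.flip_v and rng.random() < 0.5:
        pixels = pixels[::-1]
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if angle != 0.0:
        pixels = rotate(pixels, angle, mode="reflect", order=1)
    m = cfg.model_input_px
    # scale is relative to the model input size: identity parameters leave
    # exactly the plain 256→224 resize path
    scale = rng.uniform(*cfg.scale_range)
    target = max(m, int(round(m * scale)))
    pixels = resize(pixels, (target, target, 3), order=1, anti_aliasing=False)
    max_r = pixels.shape[0] - m
    max_c = pixels.shape[1] - m
    r0 = int(rng.integers(0, max_r + 1)) if max_r > 0 else 0
    c0 = int(rng.integers(0, max_c + 1)) if max_c > 0 else 0
    out = pixels[r0:r0 + m, c0:c0 + m]
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


def patch_manifest(patches: Sequence[Patch], slide_id: str) -> pd.DataFrame:
    return pd.DataFrame([{"slide_id": slide_id, "grid_row": p.grid_row,
                          "grid_col": p.grid_col,
                          "tissue_fraction": p.tissue_fraction}
                         for p in patches])
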