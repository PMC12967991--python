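"""Attention heatmaps: score rasters, iso-contours, and peak markers.

Patch attention is scattered back onto the slide's patch grid, Gaussian
smoothed, min-max rescaled to [0, 1], and summarised by marching-squares
contours at a threshold (default 0.5) plus the locations of the raster
maximum — the dashed-contour / star-marker rendering familiar from
computational-pathology activation maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours

__all__ = ["ActivationMap", "build_map", "extract_contours", "peak_points",
           "make_activation_map", "render_overlay", "contours_to_geojson"]


@dataclass
class ActivationMap:
    scores: np.ndarray                       # (rows, cols) in [0, 1]
    contours: list[np.ndarray]               # polygons, (row, col) pixel coords
    peaks: list[tuple[int, int]]
    threshold: float
    constant: bool = False                   # degenerate constant-map flag


def build_map(patch_attention: np.ndarray, coords: np.ndarray,
              grid_shape: tuple[int, int], sigma: float = 1.0
              ) -> tuple[np.ndarray, bool]:
    """Scatter attention onto the patch grid, smooth, min-max rescale.

    Returns ``(raster, constant_flag)``; a constant input map cannot be
    rescaled and comes back as all zeros with the flag set.
    """
    att = np.asarray(patch_attention, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if not np.isclose(att.sum(), 1.0, atol=1e-6):
        raise ValueError("patch attention must be normalized to sum 1")
    if np.any(coords < 0) or np.any(coords[:, 0] >= grid_shape[0]) \
            or np.any(coords[:, 1] >= grid_shape[1]):
        raise ValueError("coordinates fall outside the grid")
    raster = np.zeros(grid_shape)
    np.add.at(raster, (coords[:, 0], coords[:, 1]), att)
    if sigma > 0:
        raster = gaussian_filter(raster, sigma=sigma)
    lo, hi = raster.min(), raster.max()
    if np.isclose(hi, lo):
        return np.zeros(grid_shape), True
    return (raster - lo) / (hi - lo), False


def extract_contours(raster: np.ndarray, threshold: float
                     ) -> list[np.ndarray]:
    """Marching-squares iso-contours of the raster at ``threshold``."""
    raster = np.asarray(raster, dtype=float)
    if raster.min() < -1e-9 or raster.max() > 1 + 1e-9:
        raise ValueError("raster values must lie in [0, 1]")
    if np.allclose(raster, raster.flat[0]):
        return []
    return find_contours(raster, threshold)


def peak_points(raster: np.ndarray) -> list[tuple[int, int]]:
    """All cells attaining the raster maximum (ties all reported)."""
    raster = np.asarray(raster, dtype=float)
    peak = raster.max()
    rows, cols = np.where(np.isclose(raster, peak))
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def make_activation_map(patch_attention: np.ndarray, coords: np.ndarray,
                        grid_shape: tuple[int, int], sigma: float = 1.0,
                        threshold: float = 0.5) -> ActivationMap:
    raster, constant = build_map(patch_attention, coords, grid_shape, sigma)
    contours = [] if constant else extract_contours(raster, threshold)
    return ActivationMap(scores=raster, contours=contours,
                         peaks=peak_points(raster), threshold=threshold,
                         constant=constant)


def render_overlay(amap: ActivationMap, out_path: str | Path,
                   background: np.ndarray | None = None) -> None:
    """PNG overlay: heatmap + white dashed contours + red star peaks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background, extent=(-0.5, amap.scores.shape[1] - 0.5,
                                      amap.scores.shape[0] - 0.5, -0.5))
        ax.imshow(amap.scores, cmap="viridis", alpha=0.55)
    else:
        ax.imshow(amap.scores, cmap="viridis")
    for contour in amap.contours:
        ax.plot(contour[:, 1], contour[:, 0], "w--", linewidth=1.5)
    for r, c in amap.peaks:
        ax.plot(c, r, "r*", markersize=14)
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def contours_to_geojson(amap: ActivationMap) -> dict:
    """Polygon JSON (GeoJSON-like, 0-based (col, row) pixel coordinates)."""
    features = []
    for contour in amap.contours:
        ring = [[float(c), float(r)] for r, c in contour]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"threshold": amap.threshold},
        })
    return {"type": "FeatureCollection", "features": features,
            "peaks": [[int(c), int(r)] for r, c in amap.peaks]}
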