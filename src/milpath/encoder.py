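"""Patch → 1024-d feature bags.

The production path is a pretrained CNN backbone whose pooled embedding is
projected to 1024 dimensions by a fixed seeded linear map. Because no
pretrained weights ship with the package, the default backbone is a
deterministic *stub*: each normalized patch is average-pooled to 8×8,
flattened, passed through a fixed random linear map to 1024 dims, and
standardized against a frozen calibration batch. The stub carries real
image statistics (colour/density differences survive the pooling), which
is enough for every pipeline stage to be exercised end to end.
"""

from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np

from .bags import PatchBag
from .preprocessing import Patch, normalize_patch

__all__ = ["StubBackbone", "ProjectedBackbone", "encode_patches"]

FEATURE_DIM = 1024


class Backbone(Protocol):
    def embed(self, tensor: np.ndarray) -> np.ndarray: ...


class StubBackbone:
    """Deterministic, weight-free patch embedder.

    8×8 average pooling of the (3, H, W) normalized tensor, flatten to 192,
    fixed seeded linear map to 1024, then per-dimension standardization
    using moments frozen from a seeded calibration batch of noise patches.
    """

    def __init__(self, seed: int = 0, pool: int = 8,
                 out_dim: int = FEATURE_DIM):
        rng = np.random.default_rng(seed)
        self.pool = pool
        in_dim = 3 * pool * pool
        self.projection = rng.standard_normal((in_dim, out_dim)) / np.sqrt(in_dim)
        # calibration batch: solid-colour patches spanning the normalized
        # intensity range (tissue patches are locally near-constant after
        # 8x8 pooling, so this matches the statistics the stub will see)
        colors = rng.uniform(-2.2, 2.3, size=(256, 3))
        calib = np.repeat(colors, pool * pool, axis=1)
        calib += rng.normal(0, 0.1, size=calib.shape)
        raw = calib @ self.projection
        self._mu = raw.mean(axis=0)
        self._sd = raw.std(axis=0)
        self._sd[self._sd == 0] = 1.0

    def _pool(self, tensor: np.ndarray) -> np.ndarray:
        c, h, w = tensor.shape
        ph, pw = h // self.pool, w // self.pool
        trimmed = tensor[:, :ph * self.pool, :pw * self.pool]
        pooled = trimmed.reshape(c, self.pool, ph, self.pool, pw).mean(axis=(2, 4))
        return pooled.reshape(-1)

    def embed(self, tensor: np.ndarray) -> np.ndarray:
        raw = self._pool(tensor) @ self.projection
        return (raw - self._mu) / self._sd


class ProjectedBackbone:
    """Wrap an external embedding function with a fixed 1024-d projection.

    Reconciles backbones whose pooled embedding is not 1024-d (e.g. a
    2048-d pooled CNN feature) with the 1024-d bag contract via a seeded
    linear projection.
    """

    def __init__(self, embed_fn, in_dim: int, seed: int = 0,
                 out_dim: int = FEATURE_DIM):
        self._fn = embed_fn
        rng = np.random.default_rng(seed)
        self.projection = rng.standard_normal((in_dim, out_dim)) / np.sqrt(in_dim)

    def embed(self, tensor: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(tensor)).reshape(-1) @ self.projection


def encode_patches(patches: Sequence[Patch], backbone: Backbone | None = None,
                   slide_id: str | None = None, label: str | None = None,
                   domain: str = "wsi") -> PatchBag:
    """Encode a slide's patches into a PatchBag (row order = patch order)."""
    if len(patches) == 0:
        raise ValueError("a slide must yield at least one patch")
    backbone = backbone or StubBackbone()
    feats = np.stack([backbone.embed(normalize_patch(p)) for p in patches])
    coords = np.array([[p.grid_row, p.grid_col] for p in patches])
    return PatchBag(features=feats, coords=coords,
                    slide_id=slide_id or patches[0].slide_id or "slide",
                    label=label, domain=domain)
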