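"""Feature-space oversampling of the minority class: SMOTE and ADASYN.

Both operate on bag-level embeddings. SMOTE interpolates uniformly
between a minority point and one of its k nearest minority neighbours;
ADASYN allocates the synthesis budget G = ⌊(|maj| − |min|)·β⌋ in
proportion to each minority point's local majority density r_i, then
synthesises SMOTE-style around each point.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["smote", "adasyn", "adasyn_allocation", "SMOTESampler",
           "ADASYNSampler"]

logger = logging.getLogger(__name__)


def _minority_neighbors(X: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 minority samples to interpolate")
    if m < k + 1:
        logger.warning("k=%d too large for %d minority samples; using k=%d",
                       k, m, m - 1)
        k = m - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    return idx, k


def smote(X_min: np.ndarray, n_new: int, k: int = 5,
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate ``n_new`` synthetic minority points on kNN segments."""
    X_min = np.asarray(X_min, dtype=float)
    rng = rng or np.random.default_rng()
    if n_new == 0:
        return np.empty((0, X_min.shape[1]))
    neigh, k = _minority_neighbors(X_min, k)
    base = rng.integers(0, X_min.shape[0], size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    anchors = X_min[base]
    partners = X_min[neigh[base, pick]]
    return anchors + lam[:, None] * (partners - anchors)


def adasyn_allocation(r: np.ndarray, G: int) -> np.ndarray:
    """Per-point synthesis counts g_i = round(r̂_i · G) with r̂ = r/Σr.

    Σr = 0 (no minority point has majority neighbours) falls back to a
    uniform allocation with a logged warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("majority-neighbour ratios must be nonnegative")
    if r.sum() == 0:
        logger.warning("no majority neighbours found; uniform ADASYN allocation")
        r = np.ones_like(r)
    return np.round(r / r.sum() * G).astype(int)


def adasyn(X_min: np.ndarray, X_maj: np.ndarray, k: int = 5,
           beta: float = 1.0,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Density-adaptive oversampling of the minority class.

    r_i = fraction of majority points among each minority point's k
    nearest neighbours in the combined set; g_i = round(r̂_i · G) samples
    are synthesised around point i. If no minority point has majority
    neighbours (Σr = 0), the budget is spread uniformly with a warning.
    """
    X_min = np.asarray(X_min, dtype=float)
    X_maj = np.asarray(X_maj, dtype=float)
    rng = rng or np.random.default_rng()
    if X_min.shape[0] < 2:
        raise ValueError("need at least 2 minority samples")
    if X_min.shape[0] == 0 or X_maj.shape[0] == 0:
        raise ValueError("both classes must be nonempty")
    combined = np.vstack([X_min, X_maj])
    if combined.shape[0] <= k:
        raise ValueError("combined sample size must exceed k")
    G = int(np.floor((X_maj.shape[0] - X_min.shape[0]) * beta))
    if G <= 0:
        return np.empty((0, X_min.shape[1]))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(combined)
    idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    r = (idx >= X_min.shape[0]).mean(axis=1)
    alloc = adasyn_allocation(r, G)

    min_neigh, k_eff = _minority_neighbors(X_min, k)
    pieces = []
    for i, g_i in enumerate(alloc):
        if g_i == 0:
            continue
        pick = rng.integers(0, k_eff, size=g_i)
        lam = rng.uniform(0.0, 1.0, size=g_i)
        partners = X_min[min_neigh[i, pick]]
        pieces.append(X_min[i] + lam[:, None] * (partners - X_min[i]))
    if not pieces:
        return np.empty((0, X_min.shape[1]))
    return np.vstack(pieces)


class SMOTESampler:
    """imblearn-style wrapper: fit_resample balances the minority class."""

    def __init__(self, k_neighbors: int = 5, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"k_neighbors": self.k_neighbors, "seed": self.seed}

    def set_params(self, **params) -> "SMOTESampler":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def sample(self, X_min: np.ndarray, X_maj: np.ndarray,
               beta: float = 1.0) -> np.ndarray:
        n_new = int(np.floor((X_maj.shape[0] - X_min.shape[0]) * beta))
        if n_new <= 0:
            return np.empty((0, X_min.shape[1]))
        return smote(X_min, n_new, self.k_neighbors,
                     np.random.default_rng(self.seed))


class ADASYNSampler:
    def __init__(self, k_neighbors: int = 5, beta: float = 1.0, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.beta = beta
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"k_neighbors": self.k_neighbors, "beta": self.beta,
                "seed": self.seed}

    def set_params(self, **params) -> "ADASYNSampler":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def sample(self, X_min: np.ndarray, X_maj: np.ndarray,
               beta: float | None = None) -> np.ndarray:
        return adasyn(X_min, X_maj, self.k_neighbors,
                      self.beta if beta is None else beta,
                      np.random.default_rng(self.seed))
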