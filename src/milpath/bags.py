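"""Bag containers and on-disk cohort layout.

A *bag* is the MIL representation of one slide: an N×d matrix of per-patch
feature vectors plus the N patch-grid coordinates they came from. Cohorts
are stored one ``.npz`` file per slide (arrays ``features`` and ``coords``)
next to a ``labels.csv`` with columns slide_id, label, domain, split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DOMAINS, LABELS

__all__ = ["PatchBag", "save_bag", "load_bag", "write_bag_cohort",
           "read_bag_cohort", "write_labels", "read_labels"]


@dataclass
class PatchBag:
    """Per-patch features and grid coordinates for one slide."""

    features: np.ndarray          # (N, d) float
    coords: np.ndarray            # (N, 2) int: (grid_row, grid_col)
    slide_id: str
    label: Optional[str] = None   # Good / Medium / Bad
    domain: str = "wsi"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a nonempty (N, d) matrix")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align with features rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("bag contains non-finite feature values")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def save_bag(bag: PatchBag, path: str | Path) -> None:
    np.savez(path, features=bag.features, coords=bag.coords)


def load_bag(path: str | Path, slide_id: str | None = None,
             label: str | None = None, domain: str = "wsi") -> PatchBag:
    with np.load(path) as data:
        return PatchBag(features=data["features"], coords=data["coords"],
                        slide_id=slide_id or Path(path).stem,
                        label=label, domain=domain)


def write_labels(records: Sequence[dict], path: str | Path) -> None:
    df = pd.DataFrame(records, columns=["slide_id", "label", "domain", "split"])
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)


def write_bag_cohort(samples: Sequence[tuple[PatchBag, str, str, str]],
                     out_dir: str | Path) -> None:
    """Write one .npz per slide plus labels.csv into ``out_dir/bags``."""
    out_dir = Path(out_dir)
    bag_dir = out_dir / "bags"
    bag_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for bag, label, domain, split in samples:
        save_bag(bag, bag_dir / f"{bag.slide_id}.npz")
        records.append({"slide_id": bag.slide_id, "label": label,
                        "domain": domain, "split": split})
    write_labels(records, out_dir / "labels.csv")


def read_bag_cohort(out_dir: str | Path
                    ) -> list[tuple[PatchBag, str, str, str]]:
    out_dir = Path(out_dir)
    df = read_labels(out_dir / "labels.csv")
    samples = []
    for row in df.itertuples():
        bag = load_bag(out_dir / "bags" / f"{row.slide_id}.npz",
                       slide_id=row.slide_id, label=row.label,
                       domain=row.domain)
        samples.append((bag, row.label, row.domain, row.split))
    return samples
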