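"""Seeded synthetic cohorts: slide images and feature bags.

The generator reproduces the structural facts the pipeline assumes —
a 128-slide cohort with 60 Good / 51 Medium / 17 Bad slides split 86/42
into train/validation, plus a 22-image external domain with a resolution
and colour shift — without claiming visual realism. Slides are white
canvases with hematoxylin/eosin-toned elliptical tissue blobs whose
density and eccentricity increase from Good to Bad (a crude proxy for
residual tumour cellularity: non-responders retain dense, atypical
nuclei). Feature bags are Gaussian mixtures of an uninformative
background component and a class-specific component at a configurable
distance from the origin; the fraction of informative patches per bag is
drawn from U(0.1, 0.5), a modelling choice the source data does not pin
down.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import ellipse
from skimage.transform import resize

from .bags import PatchBag, write_bag_cohort, write_labels
from .config import DOMAINS, LABELS, CohortSpec

__all__ = ["SyntheticSlide", "generate_slide", "generate_feature_bags",
           "generate_image_cohort", "write_image_cohort", "class_proportions",
           "stratified_counts"]

# mean blob count per 1024x1024 slide; Bad > Medium > Good by construction
_BLOB_DENSITY = {"Good": 20.0, "Medium": 32.0, "Bad": 45.0}
# axis-ratio range per class (lower ratio = more eccentric nuclei proxy)
_AXIS_RATIO = {"Good": (0.70, 1.00), "Medium": (0.50, 0.90),
               "Bad": (0.30, 0.80)}
_HEMATOXYLIN = np.array([115, 65, 160], dtype=float)   # purple-blue
_EOSIN = np.array([230, 130, 170], dtype=float)        # pink


@dataclass
class SyntheticSlide:
    image: np.ndarray        # (H, W, 3) uint8
    lesion_mask: np.ndarray  # (H, W) bool
    label: str
    domain: str
    slide_id: str
    n_blobs: int = 0


def generate_slide(label: str, domain: str, size: int,
                   rng: np.random.Generator) -> SyntheticSlide:
    """Render one synthetic H&E-like slide.

    ``domain="microscope"`` additionally applies a 2x downscale/upscale blur
    and a global hue shift, emulating the scanner-vs-microscope gap.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    if size < 512:
        raise ValueError("slide size must be at least 512 px per side")

    img = np.full((size, size, 3), 255.0)
    mask = np.zeros((size, size), dtype=bool)
    lam = _BLOB_DENSITY[label] * (size / 1024.0) ** 2
    n_blobs = max(3, int(rng.poisson(lam)))
    lo_ratio, hi_ratio = _AXIS_RATIO[label]
    # blobs cluster in a biopsy-like tissue core rather than scattering
    # uniformly, so local patch-level tissue fractions are realistic
    core_r = rng.uniform(0.25, 0.45) * size
    core_c = rng.uniform(0.25, 0.45) * size + 0.15 * size
    for _ in range(n_blobs):
        r0 = np.clip(rng.normal(core_r, size / 5), 0, size)
        c0 = np.clip(rng.normal(core_c, size / 5), 0, size)
        a = rng.uniform(24, 64) * size / 1024.0
        b = a * rng.uniform(lo_ratio, hi_ratio)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, a, b, shape=(size, size), rotation=theta)
        base = _HEMATOXYLIN if rng.random() < 0.6 else _EOSIN
        color = np.clip(base + rng.normal(0, 12, size=3), 0, 255)
        img[rr, cc] = color
        mask[rr, cc] = True

    image = img
    if domain == "microscope":
        half = resize(image / 255.0, (size // 2, size // 2, 3),
                      anti_aliasing=True)
        image = resize(half, (size, size, 3), anti_aliasing=False) * 255.0
        hsv = rgb2hsv(image / 255.0)
        hsv[..., 0] = np.mod(hsv[..., 0] + 0.06, 1.0)
        image = hsv2rgb(hsv) * 255.0

    return SyntheticSlide(image=np.clip(image, 0, 255).astype(np.uint8),
                          lesion_mask=mask, label=label, domain=domain,
                          slide_id="", n_blobs=n_blobs)


def class_proportions(spec: CohortSpec) -> np.ndarray:
    total = spec.n_good + spec.n_medium + spec.n_bad
    return np.array([spec.n_good, spec.n_medium, spec.n_bad]) / total


def stratified_counts(class_counts: Sequence[int], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` across classes."""
    class_counts = np.asarray(class_counts, dtype=float)
    quota = class_counts * total / class_counts.sum()
    out = np.floor(quota).astype(int)
    remainder = quota - out
    for idx in np.argsort(-remainder)[: total - out.sum()]:
        out[idx] += 1
    return out.tolist()


def _cohort_labels_splits(spec: CohortSpec) -> list[tuple[str, str, str]]:
    """(label, domain, split) rows matching the CohortSpec exactly."""
    class_counts = [spec.n_good, spec.n_medium, spec.n_bad]
    train_counts = stratified_counts(class_counts, spec.n_train)
    ext_counts = stratified_counts(class_counts, spec.n_external)
    rows: list[tuple[str, str, str]] = []
    for label, n_total, n_tr in zip(LABELS, class_counts, train_counts):
        for i in range(n_total):
            split = "train" if i < n_tr else "val"
            rows.append((label, "wsi", split))
    for label, n_ext in zip(LABELS, ext_counts):
        rows.extend((label, "microscope", "external") for _ in range(n_ext))
    return rows


def generate_feature_bags(spec: CohortSpec,
                          bag_size_range: tuple[int, int] = (16, 64),
                          dim: int = 1024
                          ) -> list[tuple[PatchBag, str, str, str]]:
    """Draw a full cohort of feature bags from the mixture model.

    Per class c, informative patches are N(separation * u_c, I) with fixed
    orthonormal directions u_c; background patches are N(0, I). External
    bags are passed through a fixed random affine map scaled by
    ``spec.domain_shift``.
    """
    if dim <= 0:
        raise ValueError("feature dimension must be positive")
    if bag_size_range[0] < 4:
        raise ValueError("bag sizes must be at least 4")
    rng = np.random.default_rng(spec.seed)

    # fixed orthonormal class directions
    q, _ = np.linalg.qr(rng.standard_normal((dim, 3)))
    mus = {label: spec.separation * q[:, k] for k, label in enumerate(LABELS)}

    # fixed affine domain map: x -> x + shift * (S x + b)
    shift_mat = rng.standard_normal((dim, dim)) * (0.1 / np.sqrt(dim))
    shift_vec = rng.standard_normal(dim) * 0.5

    grid_side = 32
    samples: list[tuple[PatchBag, str, str, str]] = []
    for i, (label, domain, split) in enumerate(_cohort_labels_splits(spec)):
        n = int(rng.integers(bag_size_range[0], bag_size_range[1] + 1))
        frac = rng.uniform(0.1, 0.5)
        n_inf = max(1, int(round(frac * n)))
        feats = rng.standard_normal((n, dim))
        feats[:n_inf] += mus[label]
        rng.shuffle(feats, axis=0)
        if domain == "microscope":
            feats = feats + spec.domain_shift * (feats @ shift_mat.T + shift_vec)
        cells = rng.choice(grid_side * grid_side, size=n, replace=False)
        coords = np.stack([cells // grid_side, cells % grid_side], axis=1)
        bag = PatchBag(features=feats, coords=coords,
                       slide_id=f"slide_{i:04d}", label=label, domain=domain)
        samples.append((bag, label, domain, split))
    return samples


def generate_image_cohort(spec: CohortSpec, size: int = 768
                          ) -> list[SyntheticSlide]:
    """Render a full image cohort (slides carry a ``split`` attribute)."""
    rng = np.random.default_rng(spec.seed)
    slides = []
    for i, (label, domain, split) in enumerate(_cohort_labels_splits(spec)):
        slide = generate_slide(label, domain, size, rng)
        slide.slide_id = f"slide_{i:04d}"
        slide.split = split  # type: ignore[attr-defined]
        slides.append(slide)
    return slides


def write_image_cohort(slides: Sequence[SyntheticSlide],
                       out_dir: str | Path) -> None:
    """slides/*.png, masks/*.png and labels.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for slide in slides:
        Image.fromarray(slide.image).save(
            out_dir / "slides" / f"{slide.slide_id}.png")
        Image.fromarray(slide.lesion_mask.astype(np.uint8) * 255).save(
            out_dir / "masks" / f"{slide.slide_id}.png")
        records.append({"slide_id": slide.slide_id, "label": slide.label,
                        "domain": slide.domain,
                        "split": getattr(slide, "split", "train")})
    write_labels(records, out_dir / "labels.csv")


def write_feature_cohort(samples: Sequence[tuple[PatchBag, str, str, str]],
                         out_dir: str | Path) -> None:
    write_bag_cohort(samples, out_dir)
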