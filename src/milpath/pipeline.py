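"""End-to-end pipeline: simulate → (preprocess → encode) → train →
evaluate → heatmap, with every artifact stamped by config hash and seed.

Two simulation routes exist: ``bags`` draws feature bags directly from
the cohort mixture model (the default; exercises the MIL stages at full
cohort size), while ``images`` renders synthetic slides and runs the
full tissue-masking / patching / encoding front end first.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .bags import PatchBag, write_bag_cohort
from .config import RunConfig
from .encoder import StubBackbone, encode_patches
from .evaluation import evaluate_predictions
from .heatmap import contours_to_geojson, make_activation_map, render_overlay
from .preprocessing import extract_patches, tissue_mask
from .synthetic import generate_feature_bags, generate_image_cohort, \
    write_image_cohort
from .training import MILEnsembleClassifier, assert_no_leakage

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stamp(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def _simulate_bags(cfg: RunConfig, out_dir: Path, route: str
                   ) -> list[tuple[PatchBag, str, str, str]]:
    cohort = cfg.cohort.model_copy(update={"seed": cfg.seed})
    if route == "bags":
        samples = generate_feature_bags(cohort)
        write_bag_cohort(samples, out_dir / "cohort")
        return samples
    if route != "images":
        raise ValueError(f"unknown route {route!r}")
    slides = generate_image_cohort(cohort, size=768)
    write_image_cohort(slides, out_dir / "cohort")
    backbone = StubBackbone(seed=cfg.seed)
    samples = []
    manifests = []
    for slide in slides:
        mask = tissue_mask(slide.image)
        patches = extract_patches(slide.image, mask, cfg.preprocess)
        if not patches:
            logger.warning("slide %s yielded no tissue patches; skipped",
                           slide.slide_id)
            continue
        bag = encode_patches(patches, backbone, slide_id=slide.slide_id,
                             label=slide.label, domain=slide.domain)
        samples.append((bag, slide.label, slide.domain,
                        getattr(slide, "split", "train")))
        manifests.extend({"slide_id": slide.slide_id, "grid_row": p.grid_row,
                          "grid_col": p.grid_col,
                          "tissue_fraction": p.tissue_fraction}
                         for p in patches)
    pd.DataFrame(manifests).to_csv(out_dir / "patch_manifest.csv", index=False)
    write_bag_cohort(samples, out_dir / "encoded")
    return samples


def run_pipeline(cfg: RunConfig, route: str = "bags") -> Path:
    """Execute all stages; returns the artifacts directory."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    (out_dir / "config.yaml").write_text(cfg.to_yaml())
    t0 = time.time()

    stage = "simulate"
    try:
        samples = _simulate_bags(cfg, out_dir, route)
        train_bags = [b for b, _, _, s in samples if s == "train"]
        val_bags = [b for b, _, _, s in samples if s == "val"]
        ext_bags = [b for b, _, _, s in samples if s == "external"]
        assert_no_leakage([b.slide_id for b in train_bags],
                          [b.slide_id for b in val_bags],
                          [b.slide_id for b in ext_bags])

        stage = "train"
        ens = MILEnsembleClassifier(
            model=cfg.model, train=cfg.train, loss=cfg.loss,
            schedule=cfg.schedule, oversample=cfg.oversample, seed=cfg.seed)
        ens.fit(train_bags, val_bags=val_bags,
                domain_bags=ext_bags if cfg.loss.dann_use_unlabeled_external
                else None)
        histories = pd.concat(
            [m.history_.table.assign(member=i)
             for i, m in enumerate(ens.members_)], ignore_index=True)
        histories.to_csv(out_dir / "history.csv", index=False)
        member_paths = []
        for i, member in enumerate(ens.members_):
            path = out_dir / f"member_{i}.npz"
            member.save(path)
            member_paths.append(str(path))
        (out_dir / "ensemble.json").write_text(
            json.dumps({**ens.manifest(), "members": member_paths,
                        **stamp}, indent=2))

        stage = "evaluate"
        metrics = dict(stamp)
        for name, split_bags in (("validation", val_bags),
                                 ("external", ext_bags)):
            if not split_bags:
                continue
            y = [b.label for b in split_bags]
            probs = ens.predict_proba(split_bags)
            report = evaluate_predictions(y, probs)
            metrics[name] = report.to_dict()
            np.savetxt(out_dir / f"confusion_{name}.csv", report.confusion,
                       delimiter=",", fmt="%.6f")
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))

        stage = "heatmap"
        hm_dir = out_dir / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        member = ens.members_[0]
        for bag in val_bags[:3]:
            att = member.attention(bag)
            grid_shape = (int(bag.coords[:, 0].max()) + 1,
                          int(bag.coords[:, 1].max()) + 1)
            amap = make_activation_map(att, bag.coords, grid_shape)
            render_overlay(amap, hm_dir / f"{bag.slide_id}.png")
            (hm_dir / f"{bag.slide_id}.json").write_text(
                json.dumps({**contours_to_geojson(amap), **stamp}))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out_dir
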