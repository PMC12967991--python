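"""Configuration objects for every stage of the pipeline.

Defaults mirror the published training recipe: label smoothing ε=0.1,
contrastive margin 1.0, triplet margin 0.5, SMOTE k=5, AdamW lr 1e-4 /
weight decay 0.01, OneCycle max lr 3e-4 over 25,000 steps (5,000 warm-up),
batch 64 slides, early-stopping patience 10, five ensemble members.
Model sizes (embed dim, heads, layers) are desk-scale defaults; the
published work grid-searched the head count and did not print sizes.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

LABELS: tuple[str, str, str] = ("Good", "Medium", "Bad")
DOMAINS: tuple[str, str] = ("wsi", "microscope")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CohortSpec(_Strict):
    """Cohort structure: 60/51/17 classes, 86/42 train/val, 22 external."""

    n_good: int = 60
    n_medium: int = 51
    n_bad: int = 17
    n_train: int = 86
    n_val: int = 42
    n_external: int = 22
    separation: float = 6.0
    domain_shift: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        counts = (self.n_good, self.n_medium, self.n_bad,
                  self.n_train, self.n_val, self.n_external)
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be nonnegative")
        if self.n_train + self.n_val != self.n_good + self.n_medium + self.n_bad:
            raise ValueError("n_train + n_val must equal the class total")
        if self.separation < 0 or self.domain_shift < 0:
            raise ValueError("separation and domain_shift must be nonnegative")
        return self


class PreprocessConfig(_Strict):
    patch_size_px: int = 256
    model_input_px: int = 224
    norm_mean: Tuple[float, float, float] = (0.485, 0.456, 0.406)
    norm_std: Tuple[float, float, float] = (0.229, 0.224, 0.225)
    min_tissue_fraction: float = 0.25
    rotation_deg: float = 30.0
    scale_range: Tuple[float, float] = (0.8, 1.2)
    flip_h: bool = True
    flip_v: bool = True

    @model_validator(mode="after")
    def _check(self) -> "PreprocessConfig":
        if self.patch_size_px < self.model_input_px:
            raise ValueError("patch size must be >= model input size")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in [0, 1]")
        return self


class ModelConfig(_Strict):
    embed_dim: int = 128
    n_heads: int = 4
    n_layers: int = 2
    scales: Tuple[int, ...] = (4, 8, 16)
    n_classes: int = 3
    dropout: float = 0.0
    use_multiscale: bool = True  # ablation flag: plain attention-MIL when off

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        return self


class OversampleConfig(_Strict):
    method: Literal["smote", "adasyn", "none"] = "smote"
    k_neighbors: int = 5
    beta: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "OversampleConfig":
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        return self


class LossConfig(_Strict):
    label_smooth_eps: float = 0.1
    contrastive_margin: float = 1.0
    triplet_margin: float = 0.5
    dann_disc_lr: float = 1e-5
    dann_lambda: float = 1.0
    dann_lambda_schedule: Literal["constant", "ramp"] = "constant"
    dann_use_unlabeled_external: bool = False
    loss_weights: Tuple[float, float, float, float] = (1.0, 0.1, 0.1, 0.1)

    @model_validator(mode="after")
    def _check(self) -> "LossConfig":
        if not 0.0 <= self.label_smooth_eps < 1.0:
            raise ValueError("label smoothing eps must be in [0, 1)")
        if self.contrastive_margin <= 0 or self.triplet_margin <= 0:
            raise ValueError("margins must be positive")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")
        return self


class ScheduleConfig(_Strict):
    """OneCycle: cosine warm-up to max_lr, cosine anneal back to ~0."""

    max_lr: float = 3e-4
    total_steps: int = 25000
    warmup_steps: int = 5000
    div_factor: float = 1e4  # start_lr = final_lr = max_lr / div_factor

    @model_validator(mode="after")
    def _check(self) -> "ScheduleConfig":
        if not 0 < self.warmup_steps < self.total_steps:
            raise ValueError("need 0 < warmup_steps < total_steps")
        return self

    @property
    def start_lr(self) -> float:
        return self.max_lr / self.div_factor

    @property
    def final_lr(self) -> float:
        return self.max_lr / self.div_factor


class TrainConfig(_Strict):
    init_lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    max_epochs: int = 140
    patience: int = 10
    n_members: int = 5
    bootstrap: bool = True
    decision: Literal["cascade", "joint", "vote"] = "cascade"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrainConfig":
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        return self


class RunConfig(_Strict):
    """Top-level config wiring all stages; round-trips through YAML."""

    cohort: CohortSpec = CohortSpec()
    preprocess: PreprocessConfig = PreprocessConfig()
    model: ModelConfig = ModelConfig()
    oversample: OversampleConfig = OversampleConfig()
    loss: LossConfig = LossConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    train: TrainConfig = TrainConfig()
    out_dir: str = "runs/default"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()),
                              sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = json.loads(self.model_dump_json())
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
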