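"""Loss functions, gradient reversal, and the one-cycle learning-rate schedule.

Closed-form (numpy) versions are the reference API; ``*_t`` variants
operate on autodiff tensors and are what the training loop differentiates.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, gradient_reversal  # re-exported  # noqa: F401
from .config import ScheduleConfig

__all__ = ["label_smoothed_ce", "contrastive_loss", "triplet_loss",
           "onecycle_lr", "gradient_reversal", "label_smoothed_ce_t",
           "contrastive_loss_t", "triplet_loss_t", "dann_lambda"]

_CLAMP = 1e-12


def label_smoothed_ce(probs, y: int, eps: float = 0.1,
                      K: int | None = None) -> float:
    """Cross-entropy against the ε-smoothed target q = (1-ε)·one_hot + ε/K."""
    probs = np.asarray(probs, dtype=float)
    K = K or probs.shape[-1]
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    if not (0 <= y < K):
        raise ValueError("label index out of range")
    q = np.full(K, eps / K)
    q[y] += 1.0 - eps
    return float(-(q * np.log(np.clip(probs, _CLAMP, None))).sum())


def label_smoothed_ce_t(logits: Tensor, y: int, eps: float = 0.1) -> Tensor:
    """Differentiable label-smoothed CE on raw logits (numerically stable)."""
    k = logits.shape[-1]
    q = np.full(k, eps / k)
    q[y] += 1.0 - eps
    return -(logits.log_softmax(axis=-1) * q).sum()


def contrastive_loss(d: float, same_pair: bool, m: float = 1.0) -> float:
    """Pair loss on a Euclidean embedding distance: d² or max(0, m-d)²."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    if same_pair:
        return float(d * d)
    return float(max(0.0, m - d) ** 2)


def contrastive_loss_t(a: Tensor, b: Tensor, same_pair: bool,
                       m: float = 1.0) -> Tensor:
    diff = a - b
    d2 = (diff * diff).sum()
    if same_pair:
        return d2
    d = (d2 + 1e-12) ** 0.5
    return ((m - d).clip_min(0.0)) ** 2


def triplet_loss(d_ap: float, d_an: float, m: float = 0.5) -> float:
    """max(0, d(anchor,positive) − d(anchor,negative) + m)."""
    if d_ap < 0 or d_an < 0:
        raise ValueError("distances must be nonnegative")
    return float(max(0.0, d_ap - d_an + m))


def triplet_loss_t(anchor: Tensor, pos: Tensor, neg: Tensor,
                   m: float = 0.5) -> Tensor:
    d_ap = (((anchor - pos) ** 2).sum() + 1e-12) ** 0.5
    d_an = (((anchor - neg) ** 2).sum() + 1e-12) ** 0.5
    return (d_ap - d_an + m).clip_min(0.0)


def onecycle_lr(step: int, cfg: ScheduleConfig | None = None) -> float:
    """One-cycle schedule: cosine warm-up to max_lr, cosine anneal to ~0.

    The single annealing cosine naturally produces the slow-fast-slow
    "start-decreasing then annealing" shape; its midpoint sits halfway
    between max_lr and the (near-zero) final lr.
    """
    cfg = cfg or ScheduleConfig()
    if not 0 <= step <= cfg.total_steps:
        raise ValueError(f"step {step} outside [0, {cfg.total_steps}]")
    if step <= cfg.warmup_steps:
        phase = step / cfg.warmup_steps
        lo, hi = cfg.start_lr, cfg.max_lr
    else:
        phase = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
        lo, hi = cfg.final_lr, cfg.max_lr
        phase = 1.0 - phase
    return lo + (hi - lo) * 0.5 * (1.0 - math.cos(math.pi * phase))


def dann_lambda(step: int, total_steps: int, base: float = 1.0,
                schedule: str = "constant") -> float:
    """Adversarial strength λ: constant, or the standard sigmoid ramp."""
    if schedule == "constant":
        return base
    p = min(1.0, step / max(1, total_steps))
    return base * (2.0 / (1.0 + math.exp(-10.0 * p)) - 1.0)
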