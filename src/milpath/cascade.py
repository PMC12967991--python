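"""Two-stage cascade composition and the F1-weighted model ensemble.

Stage 1 separates Medium from non-Medium; stage 2 separates Good from
Bad among non-Medium slides. The two binary outputs are composed into a
three-class distribution by the law of total probability:

    P(Good)   = q · (1 − p),   P(Medium) = p,   P(Bad) = (1 − q) · (1 − p)

with p = P(Medium) from stage 1 and q = P(Good | non-Medium) from stage 2.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .config import LABELS

__all__ = ["relabel_stage1", "relabel_stage2", "compose_cascade",
           "ensemble_predict"]

logger = logging.getLogger(__name__)


def relabel_stage1(labels: Sequence[str]) -> list[int]:
    """Medium → 1; Good, Bad → 0."""
    out = []
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        out.append(1 if lab == "Medium" else 0)
    return out


def relabel_stage2(labels: Sequence[str]) -> list[int]:
    """Good → 1, Bad → 0; Medium is not a stage-2 label."""
    out = []
    for lab in labels:
        if lab == "Good":
            out.append(1)
        elif lab == "Bad":
            out.append(0)
        else:
            raise ValueError(f"stage 2 only accepts Good/Bad, got {lab!r}")
    return out


def compose_cascade(p_medium: float, q_good: float) -> np.ndarray:
    """Compose the two binary stages into (P(Good), P(Medium), P(Bad))."""
    if not (0.0 <= p_medium <= 1.0 and 0.0 <= q_good <= 1.0):
        raise ValueError("cascade inputs must be probabilities in [0, 1]")
    rest = 1.0 - p_medium
    return np.array([q_good * rest, p_medium, (1.0 - q_good) * rest])


def ensemble_predict(member_probs: np.ndarray,
                     f1_scores: Sequence[float]) -> np.ndarray:
    """F1-weighted average of member probability vectors.

    weights = f1 / Σf1; all-zero F1s fall back to equal weights with a
    logged warning.
    """
    member_probs = np.asarray(member_probs, dtype=float)
    f1 = np.asarray(f1_scores, dtype=float)
    if member_probs.ndim != 2 or member_probs.shape[0] != f1.shape[0]:
        raise ValueError("member_probs rows must match f1_scores length")
    if np.any((f1 < 0) | (f1 > 1)):
        raise ValueError("F1 scores must lie in [0, 1]")
    if not np.allclose(member_probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each member row must be a probability vector")
    total = f1.sum()
    if total == 0:
        logger.warning("all ensemble F1 scores are zero; using equal weights")
        weights = np.full(len(f1), 1.0 / len(f1))
    else:
        weights = f1 / total
    return weights @ member_probs
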