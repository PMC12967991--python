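"""The bag classifier: multi-scale attention MIL with a Transformer core.

A bag's 1024-d patch features are linearly embedded, augmented with
*region tokens* — gated-attention pools of the patches falling in each
cell of a coarsened patch grid (cell sizes 4, 8 and 16 patches, giving
three context scales) — and a learned class token. The sequence passes
through standard multi-head self-attention layers; the class token then
feeds (a) a joint 3-way linear head, (b) three one-vs-rest branch
scorers combined by weighted voting, and (c) a Good-vs-Bad scorer used
by the second cascade stage. Patch-level attention is read off the last
layer's class-token attention row, averaged over heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .bags import PatchBag
from .config import LABELS, ModelConfig

__all__ = ["MultiScaleTransMIL", "BagOutput", "branch_vote"]


@dataclass
class BagOutput:
    """Forward-pass result; tensor fields retain the autodiff graph."""

    logits3_t: Tensor
    branch_scores_t: Tensor
    stage2_score_t: Tensor
    embedding_t: Tensor
    patch_attention: np.ndarray
    scale_attention: dict[int, dict[tuple[int, int], np.ndarray]] = field(
        default_factory=dict)

    @property
    def logits3(self) -> np.ndarray:
        return self.logits3_t.data

    @property
    def branch_scores(self) -> np.ndarray:
        return self.branch_scores_t.data

    @property
    def stage2_score(self) -> float:
        return float(self.stage2_score_t.data)

    @property
    def embedding(self) -> np.ndarray:
        return self.embedding_t.data


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def branch_vote(branch_scores, branch_weights) -> np.ndarray:
    """Weighted vote across one-vs-rest branches → class probabilities.

    probabilities ∝ weight_k · sigmoid(score_k), renormalized to sum 1.
    """
    scores = np.asarray(branch_scores, dtype=float)
    weights = np.asarray(branch_weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("branch weights must be nonnegative and not all zero")
    votes = weights * _sigmoid(scores)
    total = votes.sum()
    if total == 0:
        return weights / weights.sum()
    return votes / total


class MultiScaleTransMIL(nn.Module):
    def __init__(self, cfg: ModelConfig | None = None, in_dim: int = 1024,
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.in_dim = in_dim
        rng = np.random.default_rng(seed)
        d = self.cfg.embed_dim
        self.embed = nn.Linear(in_dim, d, rng)
        self.cls_token = Tensor(rng.standard_normal(d) * 0.02,
                                requires_grad=True)
        self.scale_pools = [nn.GatedAttentionPool(d, max(16, d // 2), rng)
                            for _ in self.cfg.scales]
        self.layers = [nn.TransformerEncoderLayer(d, self.cfg.n_heads, rng,
                                                  self.cfg.dropout)
                       for _ in range(self.cfg.n_layers)]
        self.final_ln = nn.LayerNorm(d)
        self.joint_head = nn.Linear(d, self.cfg.n_classes, rng)
        self.branch_heads = [nn.Linear(d, 1, rng)
                             for _ in range(self.cfg.n_classes)]
        self.stage2_head = nn.Linear(d, 1, rng)

    # ------------------------------------------------------------------
    def forward(self, bag: PatchBag) -> BagOutput:
        if not np.all(np.isfinite(bag.features)):
            raise ValueError("bag contains non-finite features")
        n = bag.n_patches
        h = self.embed(Tensor(bag.features))            # (N, D)

        tokens = [self.cls_token.reshape(1, -1), h]
        scale_attention: dict[int, dict[tuple[int, int], np.ndarray]] = {}
        if self.cfg.use_multiscale:
            for scale, pool in zip(self.cfg.scales, self.scale_pools):
                cells: dict[tuple[int, int], list[int]] = {}
                for i, (r, c) in enumerate(bag.coords):
                    cells.setdefault((int(r) // scale, int(c) // scale),
                                     []).append(i)
                per_cell: dict[tuple[int, int], np.ndarray] = {}
                region_tokens = []
                for cell in sorted(cells):
                    idx = np.array(cells[cell])
                    pooled, attn = pool(h[idx])
                    per_cell[cell] = attn.data.copy()
                    region_tokens.append(pooled.reshape(1, -1))
                tokens.extend(region_tokens)
                scale_attention[scale] = per_cell
        x = concat(tokens, axis=0)

        for layer in self.layers:
            x = layer(x)
        x = self.final_ln(x)

        # class-token attention to patch tokens, averaged over heads
        last = self.layers[-1].attn.last_attention   # (H, T, T)
        att = last[:, 0, 1:1 + n].mean(axis=0)
        total = att.sum()
        patch_attention = att / total if total > 0 else np.full(n, 1.0 / n)

        cls = x[0]
        branch = concat([head(cls.reshape(1, -1)).reshape(1)
                         for head in self.branch_heads], axis=0)
        return BagOutput(
            logits3_t=self.joint_head(cls),
            branch_scores_t=branch,
            stage2_score_t=self.stage2_head(cls.reshape(1, -1)).reshape(()),
            embedding_t=cls,
            patch_attention=patch_attention,
            scale_attention=scale_attention,
        )

    __call__ = forward

    # ------------------------------------------------------------------
    def heads_on_embedding(self, emb: Tensor
                           ) -> tuple[Tensor, Tensor, Tensor]:
        """Run only the classification heads on a (D,) bag embedding.

        Used for synthetic oversampled embeddings, which have no patch
        structure and therefore never touch the attention layers.
        """
        branch = concat([head(emb.reshape(1, -1)).reshape(1)
                         for head in self.branch_heads], axis=0)
        return (self.joint_head(emb), branch,
                self.stage2_head(emb.reshape(1, -1)).reshape(()))

    # ------------------------------------------------------------------
    def predict_probs(self, out: BagOutput, decision: str = "cascade",
                      branch_weights=None) -> np.ndarray:
        from .cascade import compose_cascade  # local import avoids a cycle

        if decision == "joint":
            z = out.logits3 - out.logits3.max()
            e = np.exp(z)
            return e / e.sum()
        if decision == "vote":
            weights = (np.ones(3) if branch_weights is None
                       else np.asarray(branch_weights, float))
            return branch_vote(out.branch_scores, weights)
        if decision == "cascade":
            p_medium = float(_sigmoid(out.branch_scores[
                LABELS.index("Medium")]))
            q_good = float(_sigmoid(out.stage2_score))
            return compose_cascade(p_medium, q_good)
        raise ValueError(f"unknown decision mode {decision!r}")
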