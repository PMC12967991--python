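"""End-to-end fitting: single members, the five-model ensemble, grid search.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``), with a bag list standing in for the
usual feature matrix. A *batch* counts slides; variable bag sizes are
handled by per-bag forward passes whose losses are averaged before one
optimizer step. The one-cycle schedule spans the planned number of
optimizer steps (capped at the configured 25,000; the final learning rate
is held if training runs longer). Model selection — early stopping, grid
search, ensemble weighting — uses validation macro-F1 throughout.

Leakage guard: validation/external slide ids are asserted disjoint from
the training set, and the oversampling pool is built from training bags
only; synthetic embeddings never carry a validation or external tag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .autodiff import Tensor, gradient_reversal
from .bags import PatchBag
from .cascade import ensemble_predict
from .config import (LABELS, LossConfig, ModelConfig, OversampleConfig,
                     ScheduleConfig, TrainConfig)
from .evaluation import macro_f1
from .imbalance import adasyn, smote
from .mil_model import MultiScaleTransMIL
from .objectives import (contrastive_loss_t, dann_lambda,
                         label_smoothed_ce_t, onecycle_lr, triplet_loss_t)

__all__ = ["MILResponseClassifier", "MILEnsembleClassifier", "train_member",
           "train_ensemble", "grid_search", "assert_no_leakage"]

logger = logging.getLogger(__name__)

_DOMAIN_INDEX = {"wsi": 0, "microscope": 1}


def assert_no_leakage(train_ids, val_ids, external_ids=()) -> None:
    """Raise if any validation/external slide id appears in the training set."""
    train_ids, val_ids = set(train_ids), set(val_ids)
    external_ids = set(external_ids)
    overlap = train_ids & (val_ids | external_ids)
    if overlap:
        raise RuntimeError(
            f"train/validation leakage: shared slide ids {sorted(overlap)}")


def _binary_logits(score: Tensor) -> Tensor:
    """Lift a scalar logit to 2-class logits (0, s): softmax = (1-σ(s), σ(s))."""
    from .autodiff import concat
    zero = score.reshape(1) * 0.0
    return concat([zero, score.reshape(1)], axis=0)


@dataclass
class TrainHistory:
    table: pd.DataFrame
    best_epoch: int
    total_steps: int


class MILResponseClassifier(BaseEstimator, ClassifierMixin):
    """Single multi-scale attention-MIL bag classifier.

    Parameters are grouped into the package's config objects; any may be
    replaced wholesale via ``set_params``. ``decision`` picks how the three
    heads combine at inference: the two-stage ``cascade`` (default), the
    ``joint`` softmax head, or the branch ``vote``.
    """

    def __init__(self, model: ModelConfig | None = None,
                 train: TrainConfig | None = None,
                 loss: LossConfig | None = None,
                 schedule: ScheduleConfig | None = None,
                 oversample: OversampleConfig | None = None,
                 seed: int = 0, verbose: bool = False):
        self.model = model
        self.train = train
        self.loss = loss
        self.schedule = schedule
        self.oversample = oversample
        self.seed = seed
        self.verbose = verbose

    # -- config plumbing ----------------------------------------------------
    def _cfgs(self):
        train_cfg = self.train or TrainConfig()
        # OneCycle peak defaults to 3x the initial lr (3e-4 at the default
        # 1e-4), so the grid-searched initial lr scales the whole cycle
        schedule = self.schedule or ScheduleConfig(
            max_lr=3.0 * train_cfg.init_lr)
        return (self.model or ModelConfig(), train_cfg,
                self.loss or LossConfig(), schedule,
                self.oversample or OversampleConfig())

    # -- losses -------------------------------------------------------------
    def _classification_loss(self, model: MultiScaleTransMIL, logits3_t,
                             branch_t, stage2_t, label: str,
                             eps: float) -> Tensor:
        y3 = LABELS.index(label)
        total = label_smoothed_ce_t(logits3_t, y3, eps)
        for k in range(3):
            target = 1 if y3 == k else 0
            total = total + label_smoothed_ce_t(
                _binary_logits(branch_t[k]), target, eps)
        if label != "Medium":
            total = total + label_smoothed_ce_t(
                _binary_logits(stage2_t), 1 if label == "Good" else 0, eps)
        return total

    # -- fitting ------------------------------------------------------------
    def fit(self, bags: list[PatchBag], y=None, val_bags=None, val_y=None,
            domain_bags: list[PatchBag] | None = None):
        model_cfg, train_cfg, loss_cfg, sched_cfg, over_cfg = self._cfgs()
        y = [b.label for b in bags] if y is None else list(y)
        if len(bags) == 0:
            raise ValueError("training set is empty")
        if len(y) != len(bags):
            raise ValueError("labels must align with bags")

        rng = np.random.default_rng(self.seed)
        if val_bags is None:
            # stratified 80/20 hold-out for model selection
            idx = np.arange(len(bags))
            val_idx: list[int] = []
            for cls in LABELS:
                cls_idx = [i for i in idx if y[i] == cls]
                rng.shuffle(cls_idx)
                val_idx.extend(cls_idx[: max(1, len(cls_idx) // 5)]
                               if cls_idx else [])
            val_set = set(val_idx)
            val_bags = [bags[i] for i in idx if i in val_set]
            val_y = [y[i] for i in idx if i in val_set]
            bags = [bags[i] for i in idx if i not in val_set]
            y = [y[i] for i in idx if i not in val_set]
        val_y = [b.label for b in val_bags] if val_y is None else list(val_y)

        assert_no_leakage([b.slide_id for b in bags],
                          [b.slide_id for b in val_bags],
                          [b.slide_id for b in (domain_bags or [])])
        missing = set(LABELS) - set(val_y)
        if missing:
            logger.warning("validation set missing classes %s; macro-F1 over "
                           "present classes", sorted(missing))

        n_train = len(bags)
        steps_per_epoch = int(np.ceil(n_train / train_cfg.batch_size))
        planned = train_cfg.max_epochs * steps_per_epoch
        span = min(planned, sched_cfg.total_steps)
        warmup = max(1, round(span * sched_cfg.warmup_steps
                              / sched_cfg.total_steps))
        eff_sched = ScheduleConfig(max_lr=sched_cfg.max_lr, total_steps=span,
                                   warmup_steps=min(warmup, span - 1) or 1,
                                   div_factor=sched_cfg.div_factor)

        in_dim = bags[0].dim
        model = MultiScaleTransMIL(model_cfg, in_dim=in_dim, seed=self.seed)
        opt = nn.AdamW(model.parameters(), lr=train_cfg.init_lr,
                       weight_decay=train_cfg.weight_decay)
        disc = nn.MLP([model_cfg.embed_dim, 32, 2],
                      np.random.default_rng(self.seed + 7919))
        disc_opt = nn.AdamW(disc.parameters(), lr=loss_cfg.dann_disc_lr,
                            weight_decay=0.0)

        w_cls, w_con, w_tri, w_dom = loss_cfg.loss_weights
        train_domains = {b.domain for b in bags}
        use_dann = w_dom > 0 and (
            len(train_domains) > 1
            or (loss_cfg.dann_use_unlabeled_external and domain_bags))
        dom_pool = list(bags) + list(domain_bags or []) if use_dann else []

        history_rows = []
        best_f1, best_epoch, best_state, bad_epochs = -np.inf, 0, None, 0
        step = 0
        y_idx = np.array([LABELS.index(lab) for lab in y])

        for epoch in range(1, train_cfg.max_epochs + 1):
            model.train()
            order = rng.permutation(n_train)

            # per-epoch oversampling pool from *training* Bad embeddings only
            synthetic: np.ndarray | None = None
            if over_cfg.method != "none":
                model.eval()
                min_idx = np.where(y_idx == LABELS.index("Bad"))[0]
                minority = np.stack([model(bags[i]).embedding
                                     for i in min_idx]) if len(min_idx) \
                    else np.empty((0, model_cfg.embed_dim))
                if over_cfg.method == "adasyn":
                    maj_idx = np.where(y_idx != LABELS.index("Bad"))[0]
                    majority = np.stack([model(bags[i]).embedding
                                         for i in maj_idx])
                else:
                    majority = np.empty((max(len(bags) - len(min_idx), 0),
                                         model_cfg.embed_dim))
                model.train()
                over_rng = np.random.default_rng(over_cfg.seed + epoch)
                try:
                    if over_cfg.method == "smote":
                        n_new = max(0, majority.shape[0] - minority.shape[0])
                        synthetic = smote(minority, n_new,
                                          over_cfg.k_neighbors, over_rng)
                    else:
                        synthetic = adasyn(minority, majority,
                                           over_cfg.k_neighbors,
                                           over_cfg.beta, over_rng)
                except ValueError as exc:
                    logger.warning("oversampling skipped: %s", exc)
                if synthetic is not None and len(synthetic) == 0:
                    synthetic = None

            cls_loss_sums = {lab: 0.0 for lab in LABELS}
            cls_loss_counts = {lab: 0 for lab in LABELS}

            for start in range(0, n_train, train_cfg.batch_size):
                batch = order[start:start + train_cfg.batch_size]
                losses = []
                embeddings = []
                batch_labels = []
                for i in batch:
                    out = model(bags[i])
                    cls_l = self._classification_loss(
                        model, out.logits3_t, out.branch_scores_t,
                        out.stage2_score_t, y[i], loss_cfg.label_smooth_eps)
                    losses.append(w_cls * cls_l)
                    embeddings.append(out.embedding_t)
                    batch_labels.append(y[i])
                    cls_loss_sums[y[i]] += float(cls_l.data)
                    cls_loss_counts[y[i]] += 1

                # synthetic minority embeddings → heads only
                if synthetic is not None:
                    n_syn = min(len(synthetic),
                                max(1, len(batch) // 4))
                    take = rng.integers(0, len(synthetic), size=n_syn)
                    for emb in synthetic[take]:
                        j3, br, s2 = model.heads_on_embedding(Tensor(emb))
                        losses.append(w_cls * self._classification_loss(
                            model, j3, br, s2, "Bad",
                            loss_cfg.label_smooth_eps))

                # metric-learning losses on bag embeddings
                if w_con > 0 and len(batch) >= 2:
                    k = min(len(batch), 8)
                    for _ in range(k):
                        a, b = rng.integers(0, len(batch), size=2)
                        if a == b:
                            continue
                        losses.append(w_con * contrastive_loss_t(
                            embeddings[a], embeddings[b],
                            batch_labels[a] == batch_labels[b],
                            loss_cfg.contrastive_margin))
                if w_tri > 0 and len(set(batch_labels)) >= 2:
                    by_class: dict[str, list[int]] = {}
                    for j, lab in enumerate(batch_labels):
                        by_class.setdefault(lab, []).append(j)
                    eligible = [c for c, lst in by_class.items()
                                if len(lst) >= 2]
                    for _ in range(min(len(batch), 8)):
                        if not eligible:
                            break
                        cls = eligible[rng.integers(0, len(eligible))]
                        anc, pos = rng.choice(by_class[cls], 2, replace=False)
                        negs = [j for j, lab in enumerate(batch_labels)
                                if lab != cls]
                        neg = negs[rng.integers(0, len(negs))]
                        losses.append(w_tri * triplet_loss_t(
                            embeddings[anc], embeddings[pos],
                            embeddings[neg], loss_cfg.triplet_margin))

                # domain-adversarial branch
                if use_dann and dom_pool:
                    lam = dann_lambda(step, span, loss_cfg.dann_lambda,
                                      loss_cfg.dann_lambda_schedule)
                    n_dom = min(len(dom_pool), max(2, len(batch) // 2))
                    take = rng.integers(0, len(dom_pool), size=n_dom)
                    for j in take:
                        dbag = dom_pool[j]
                        demb = model(dbag).embedding_t
                        logits = disc(gradient_reversal(demb, lam))
                        losses.append(w_dom * label_smoothed_ce_t(
                            logits, _DOMAIN_INDEX[dbag.domain], 0.0))

                total = losses[0]
                for l in losses[1:]:
                    total = total + l
                total = total * (1.0 / len(batch))

                opt.zero_grad()
                disc_opt.zero_grad()
                total.backward()
                opt.lr = onecycle_lr(min(step, span), eff_sched)
                opt.step()
                if use_dann:
                    disc_opt.step()
                step += 1

            # ---- validation & early stopping -----------------------------
            val_pred = self.predict_with(model, val_bags, train_cfg.decision)
            val_acc = float(np.mean(np.asarray(val_pred) == np.asarray(val_y)))
            f1 = macro_f1(val_y, val_pred)
            history_rows.append({
                "epoch": epoch,
                **{f"train_loss_{lab.lower()}":
                   (cls_loss_sums[lab] / cls_loss_counts[lab]
                    if cls_loss_counts[lab] else np.nan) for lab in LABELS},
                "val_accuracy": val_acc, "val_macro_f1": f1,
            })
            if self.verbose:
                logger.info("epoch %d: val acc %.3f, macro-F1 %.3f",
                            epoch, val_acc, f1)
            if f1 > best_f1:
                best_f1, best_epoch, bad_epochs = f1, epoch, 0
                best_state = model.state_dict()
            else:
                bad_epochs += 1
                if bad_epochs >= train_cfg.patience:
                    break

        if best_state is not None:
            model.load_state_dict(best_state)
        model.eval()
        self.model_ = model
        self.classes_ = np.array(LABELS)
        self.history_ = TrainHistory(table=pd.DataFrame(history_rows),
                                     best_epoch=best_epoch,
                                     total_steps=step)
        self.val_macro_f1_ = best_f1 if np.isfinite(best_f1) else 0.0
        self.decision_ = train_cfg.decision
        return self

    # -- inference ----------------------------------------------------------
    def predict_with(self, model: MultiScaleTransMIL, bags, decision: str
                     ) -> list[str]:
        model.eval()
        probs = np.stack([model.predict_probs(model(b), decision)
                          for b in bags])
        return [LABELS[i] for i in probs.argmax(axis=1)]

    def predict_proba(self, bags: list[PatchBag]) -> np.ndarray:
        self._check_fitted()
        self.model_.eval()
        return np.stack([self.model_.predict_probs(self.model_(b),
                                                   self.decision_)
                         for b in bags])

    def predict(self, bags: list[PatchBag]) -> np.ndarray:
        return self.classes_[self.predict_proba(bags).argmax(axis=1)]

    def attention(self, bag: PatchBag) -> np.ndarray:
        self._check_fitted()
        self.model_.eval()
        return self.model_(bag).patch_attention

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights plus the embedded model config and seed."""
        import json

        self._check_fitted()
        meta = {"model": (self.model or ModelConfig()).model_dump(),
                "in_dim": self.model_.in_dim, "seed": self.seed,
                "decision": self.decision_,
                "val_macro_f1": self.val_macro_f1_}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.model_.state_dict())

    @classmethod
    def load(cls, path) -> "MILResponseClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model_cfg = ModelConfig(**meta["model"])
        clf = cls(model=model_cfg, seed=meta["seed"])
        clf.model_ = MultiScaleTransMIL(model_cfg, in_dim=meta["in_dim"],
                                        seed=meta["seed"])
        clf.model_.load_state_dict(state)
        clf.model_.eval()
        clf.classes_ = np.array(LABELS)
        clf.decision_ = meta["decision"]
        clf.val_macro_f1_ = meta["val_macro_f1"]
        return clf


class MILEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Five-member ensemble: seeds seed+0…seed+4, optional bootstrap
    resampling of the training bags, F1-weighted soft voting."""

    def __init__(self, model: ModelConfig | None = None,
                 train: TrainConfig | None = None,
                 loss: LossConfig | None = None,
                 schedule: ScheduleConfig | None = None,
                 oversample: OversampleConfig | None = None,
                 seed: int = 0, verbose: bool = False):
        self.model = model
        self.train = train
        self.loss = loss
        self.schedule = schedule
        self.oversample = oversample
        self.seed = seed
        self.verbose = verbose

    def fit(self, bags: list[PatchBag], y=None, val_bags=None, val_y=None,
            domain_bags=None):
        train_cfg = self.train or TrainConfig()
        y = [b.label for b in bags] if y is None else list(y)
        self.members_ = []
        f1s = []
        for m in range(train_cfg.n_members):
            member_seed = self.seed + m
            if train_cfg.bootstrap and train_cfg.n_members > 1:
                boot_rng = np.random.default_rng(member_seed)
                take = boot_rng.integers(0, len(bags), size=len(bags))
                m_bags = [bags[i] for i in take]
                m_y = [y[i] for i in take]
            else:
                m_bags, m_y = list(bags), list(y)
            member = MILResponseClassifier(
                model=self.model, train=train_cfg, loss=self.loss,
                schedule=self.schedule, oversample=self.oversample,
                seed=member_seed, verbose=self.verbose)
            member.fit(m_bags, m_y, val_bags=val_bags, val_y=val_y,
                       domain_bags=domain_bags)
            self.members_.append(member)
            f1s.append(member.val_macro_f1_)
        f1s = np.asarray(f1s, dtype=float)
        if f1s.sum() == 0:
            logger.warning("all member F1 scores are zero; equal weights")
            self.weights_ = np.full(len(f1s), 1.0 / len(f1s))
        else:
            self.weights_ = f1s / f1s.sum()
        self.member_f1s_ = f1s
        self.classes_ = np.array(LABELS)
        return self

    def predict_proba(self, bags: list[PatchBag]) -> np.ndarray:
        member_probs = np.stack([m.predict_proba(bags)
                                 for m in self.members_])   # (M, n, 3)
        return np.stack([
            ensemble_predict(member_probs[:, i, :], self.member_f1s_)
            for i in range(member_probs.shape[1])])

    def predict(self, bags: list[PatchBag]) -> np.ndarray:
        return self.classes_[self.predict_proba(bags).argmax(axis=1)]

    def manifest(self) -> dict:
        return {"n_members": len(self.members_),
                "val_macro_f1": self.member_f1s_.tolist(),
                "weights": self.weights_.tolist()}


# -- thin functional wrappers ------------------------------------------------

def train_member(train_bags, val_bags, model=None, train=None, loss=None,
                 schedule=None, oversample=None, seed: int = 0
                 ) -> tuple[MILResponseClassifier, TrainHistory]:
    clf = MILResponseClassifier(model=model, train=train, loss=loss,
                                schedule=schedule, oversample=oversample,
                                seed=seed)
    clf.fit(train_bags, val_bags=val_bags)
    return clf, clf.history_


def train_ensemble(train_bags, val_bags, model=None, train=None, loss=None,
                   schedule=None, oversample=None, seed: int = 0
                   ) -> MILEnsembleClassifier:
    ens = MILEnsembleClassifier(model=model, train=train, loss=loss,
                                schedule=schedule, oversample=oversample,
                                seed=seed)
    ens.fit(train_bags, val_bags=val_bags)
    return ens


def grid_search(train_bags, val_bags, grid: dict[str, list],
                model=None, train=None, loss=None, schedule=None,
                oversample=None, seed: int = 0
                ) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over {init_lr, batch_size, n_heads} on validation
    macro-F1; ties break to smaller init_lr, then smaller batch size."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    allowed = {"init_lr", "batch_size", "n_heads"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unsupported grid keys: {sorted(unknown)}")
    keys = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        t_cfg = (train or TrainConfig()).model_copy(
            update={k: params[k] for k in ("init_lr", "batch_size")
                    if k in params})
        m_cfg = (model or ModelConfig())
        if "n_heads" in params:
            m_cfg = m_cfg.model_copy(update={"n_heads": params["n_heads"]})
        clf = MILResponseClassifier(model=m_cfg, train=t_cfg, loss=loss,
                                    schedule=schedule, oversample=oversample,
                                    seed=seed)
        clf.fit(train_bags, val_bags=val_bags)
        rows.append({**params, "val_macro_f1": clf.val_macro_f1_})
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["val_macro_f1", "init_lr", "batch_size"]
        if {"init_lr", "batch_size"} <= set(table.columns)
        else ["val_macro_f1"],
        ascending=[False, True, True]
        if {"init_lr", "batch_size"} <= set(table.columns) else [False],
        kind="mergesort")
    best = {k: ranked.iloc[0][k] for k in keys}
    return best, table
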