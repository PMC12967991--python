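# milpath

Transformer-based multiple-instance learning (MIL) for predicting
neoadjuvant-chemotherapy (NAC) response from H&E-stained slide images,
as a three-class problem: **Good** (pathologic complete response,
Miller-Payne grade 5), **Medium** (partial response, grades 2–4), and
**Bad** (no response, grade 1). The package is aimed at computational
pathology researchers who want a fully automated, testable
implementation of this pipeline — including the preprocessing front end,
the bag classifier, the imbalance/domain-adaptation/metric-learning
training recipe, evaluation, and attention heatmaps — exercisable end to
end on seeded synthetic cohorts with no downloads.

## The model

A slide is a *bag* {x₁, …, x_N} of 1024-d patch features with grid
coordinates. The classifier is a multi-scale attention Transformer:

- patch features are linearly embedded; for each scale s ∈ {4, 8, 16},
  tokens grouped by ⌊grid/s⌋ cells are pooled by gated attention
  (aᵢ ∝ exp(wᵀ(tanh(Vhᵢ) ⊙ σ(Uhᵢ)))) into region tokens;
- a class token, the patch tokens and the region tokens pass through
  standard multi-head self-attention layers;
- the class token feeds a joint 3-way head, three one-vs-rest branch
  scorers combined by weighted voting, and a Good-vs-Bad scorer.

Inference defaults to the **two-stage cascade**: stage 1 scores
p = P(Medium); stage 2 scores q = P(Good | non-Medium); by total
probability

    P(Good) = q(1−p),  P(Medium) = p,  P(Bad) = (1−q)(1−p).

Training uses label-smoothed cross-entropy (ε = 0.1), contrastive
(m = 1.0) and triplet (m = 0.5) losses on bag embeddings, an optional
domain-adversarial branch (DANN, gradient reversal, discriminator lr
1e-5) to align scanner and microscope domains, SMOTE (k = 5) / ADASYN
oversampling of the minority Bad class in embedding space, AdamW
(lr 1e-4, weight decay 0.01) under a one-cycle schedule (peak 3e-4),
early stopping (patience 10) on validation macro-F1, and a five-member
bootstrap ensemble soft-voted with weights ∝ validation macro-F1. The
network and training loop run on a small, finite-difference-verified
numpy autodiff core, so CPU runs are exactly reproducible from a seed.

See `docs/methods.md` for assumptions, parameter meanings, and the
design decisions taken where the procedure was open.

## Worked example

Generate the study-structured synthetic cohort (60/51/17 slides,
86/42 train/validation split, class signal planted at separation 6 in
feature space) and train a single desk-scale classifier:

```python
import numpy as np
from milpath import (CohortSpec, ModelConfig, TrainConfig,
                     generate_feature_bags, MILResponseClassifier,
                     evaluate_predictions)

samples = generate_feature_bags(CohortSpec(separation=6.0, seed=0))
train = [bag for bag, _, _, split in samples if split == "train"]
val = [bag for bag, _, _, split in samples if split == "val"]

clf = MILResponseClassifier(
    model=ModelConfig(embed_dim=64, n_heads=4, n_layers=2),
    train=TrainConfig(batch_size=8, max_epochs=30, patience=10),
    seed=0)
clf.fit(train, val_bags=val)

report = evaluate_predictions([b.label for b in val], clf.predict_proba(val))
print(f"validation accuracy: {report.overall_accuracy:.3f}")
for cls, m in report.per_class.items():
    print(f"{cls:>6}: precision {m['precision']:.2f}  recall {m['recall']:.2f}  "
          f"F1 {m['f1']:.2f}  ROC AUC {report.roc[cls]['auc']:.2f}")
print("row-normalized confusion (Good/Medium/Bad):")
print(np.round(report.confusion, 2))
```

Output (a couple of minutes on one CPU core):

```
validation accuracy: 0.905
  Good: precision 0.86  recall 0.95  F1 0.90  ROC AUC 0.98
Medium: precision 0.94  recall 1.00  F1 0.97  ROC AUC 1.00
   Bad: precision 1.00  recall 0.40  F1 0.57  ROC AUC 0.98
row-normalized confusion (Good/Medium/Bad):
[[0.95 0.05 0.  ]
 [0.   1.   0.  ]
 [0.6  0.   0.4 ]]
```

The planted signal is recovered almost perfectly for the two majority
classes; the 5-slide Bad validation group shows the minority-class
difficulty that motivates the oversampling and cascade machinery
(per-class AUCs stay high even where the argmax decision misses).

`MILEnsembleClassifier` trains the five-member ensemble with the same
interface, and the `milpath` CLI wires the stages together
(`simulate`, `preprocess`, `encode`, `train`, `evaluate`, `heatmap`,
`gridsearch`, `run`), configured by a YAML file mirroring every printed
hyperparameter (see `milpath.config.RunConfig`).

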