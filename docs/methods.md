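# Methods

`milpath` implements a slide-level three-class classifier of neoadjuvant
chemotherapy (NAC) response — Good (pathologic complete response, Miller-Payne
grade 5), Medium (partial response, grades 2–4), Bad (no response, grade 1) —
from H&E histology under the multiple-instance learning (MIL) paradigm: a
slide is a *bag* of unlabeled 256×256-px patches, and only the bag carries a
label. This note records the model, its assumptions, the tunable parameters,
and the design decisions taken where the procedure was genuinely open.

## Pipeline

1. **Tissue masking.** Pixels are tissue iff HSV saturation exceeds the Otsu
   threshold of the saturation channel; the mask is morphologically closed
   with a 5-px disk. This automates what is often done by expert review;
   expert masks can be substituted wherever a mask argument is accepted.
2. **Patching.** Non-overlapping 256-px windows on a fixed grid from the
   top-left origin (0-based, row-major, half-open); borders narrower than one
   patch are discarded. A patch is kept iff its tissue fraction ≥
   `min_tissue_fraction` (default 0.25 — a choice, exposed in config; whether
   the original procedure filtered at all is unknown).
3. **Normalization.** Bilinear resize 256→224, scale to [0, 1], channel
   whitening with the ImageNet constants mean (0.485, 0.456, 0.406) / std
   (0.229, 0.224, 0.225).
4. **Augmentation** (training only), in a fixed order since the source lists
   the operations without one: independent 0.5-probability horizontal and
   vertical flips, rotation uniform in ±30° with reflect padding, isotropic
   scaling in [0.8, 1.2] relative to the model input size, random 224-crop.
   With identity parameters the result is exactly the plain resize path.
5. **Encoding.** Each patch becomes a 1024-d feature vector. The production
   path wraps any pretrained CNN embedding behind a fixed seeded linear
   projection to 1024 dims (`ProjectedBackbone`; a typical pooled CNN
   embedding is 2048-d, and whether the original 1024-d vector was a
   truncated layer or a projection is unstated — we chose projection). The
   default `StubBackbone` is deterministic and weight-free: 8×8 average
   pooling, a fixed random linear map to 1024 dims, and per-dimension
   standardization against a frozen calibration batch of solid-colour
   patches. It preserves colour/density statistics, which is all the
   synthetic cohorts encode.

## Bag classifier

Patch features (N×1024) are linearly embedded to `embed_dim` (default 128;
tests and the acceptance runs use 64 — "desk scale"). For each scale
s ∈ {4, 8, 16}, patch tokens are grouped by ⌊grid/s⌋ cells and pooled within
each cell by gated attention (a_i ∝ exp(wᵀ(tanh(Vh_i) ⊙ σ(Uh_i)))), yielding
region tokens that give the sequence multi-scale context. The stated scales
are ambiguous between pixels and patches; we read them as patch-grid cell
sizes (4×4 patches ≈ 1024 px at level 0), the only reading that yields
multi-scale context over a bag. A learned class token, the patch tokens and
all region tokens then pass through `n_layers` (default 2) pre-norm
Transformer layers with exact multi-head self-attention (the original
TransMIL line of work uses Nyström attention for gigapixel bags; desk-scale
bags are small enough for the exact form, a deliberate divergence). Patch
attention is the last layer's class-token attention row over patch tokens,
averaged across heads and renormalized.

Three heads read the class token:

- a joint 3-way linear head;
- three one-vs-rest branch scorers combined by weighted voting
  (probabilities ∝ w_k · σ(score_k), renormalized);
- a Good-vs-Bad scorer for the cascade's second stage.

**Two-stage cascade.** Stage 1 separates Medium from non-Medium (the Medium
branch scorer); stage 2 separates Good from Bad (trained on Good/Bad slides
only — whether the original trained stage 2 on all slides with a masked loss
is unstated). The composition rule is the law of total probability,

  P(Good) = q(1−p), P(Medium) = p, P(Bad) = (1−q)(1−p),

with p = P(Medium), q = P(Good | non-Medium) — the unique composition
consistent with the two binary stages, which the source does not spell out.
`decision` selects cascade (default), joint, or vote at inference; how the
branch vote and the cascade were combined originally is unstated, so all
three are exposed.

## Losses and optimization

Total loss = w·(classification, contrastive, triplet, domain), default
weights (1.0, 0.1, 0.1, 0.1) (unstated originally; exposed in config).

- **Classification:** label-smoothed cross-entropy, ε = 0.1, applied to the
  joint head, each binary branch, and the stage-2 head.
- **Metric learning:** contrastive loss (d² for same-class pairs,
  max(0, m−d)² otherwise, m = 1.0) and triplet loss (max(0, d_ap−d_an+m),
  m = 0.5) on *bag* embeddings with random in-batch pairs/triplets. The
  original mentions "patch feature separability"; patch-level mining with
  inherited bag labels would be the alternative reading, and bag-level was
  chosen as the less assumption-laden default.
- **Domain adaptation (DANN):** a 2-layer MLP domain discriminator on bag
  embeddings behind a gradient-reversal layer (forward identity, backward
  −λ·g), discriminator optimized separately with AdamW at lr 1e-5. λ is
  constant 1 by default with an optional sigmoid ramp. Because the training
  contract forbids any validation/external slide from contributing a
  gradient step, the adversarial branch by default sees only training-split
  domain tags; `dann_use_unlabeled_external` opts external bags (labels
  never used) into the domain loss only.
- **Optimizer/schedule:** AdamW (initial lr 1e-4, weight decay 0.01);
  one-cycle schedule with cosine warm-up to max_lr = 3e-4 over the first
  fifth of the cycle and a cosine anneal to max_lr/10⁴ ≈ 0 — the
  slow-fast-slow "start-decreasing then annealing" shape. The published
  cycle is 25,000 steps with a 5,000-step warm-up; a desk-scale run plans
  far fewer optimizer steps, so the cycle span adapts to the planned steps
  (capped at 25,000, final lr held beyond). When no explicit schedule is
  given, the peak is 3× the initial lr so that a grid-searched initial lr
  scales the whole cycle. A *batch* counts slides (default 64); per-bag
  losses are averaged before one optimizer update, and the scheduler is
  consumed exactly once per update.
- **Early stopping:** patience 10 epochs on validation macro-F1 (also the
  grid-search and ensemble-weighting metric; macro chosen over micro, which
  the source leaves open), best-epoch weights restored.

**Imbalance handling.** The Bad class (17 of 128) is oversampled in feature
space: SMOTE (k = 5) or ADASYN (β = 1) on bag-level class-token embeddings,
recomputed each epoch. Synthetic embeddings have no patch structure, so they
enter only the classification heads, never the attention layers, and are
never written to cohort files or tagged with a validation split. The space
in which the original oversampled is unstated; feature space is the only
tractable reading for MIL.

**Ensemble.** Five members with seeds seed+0…seed+4 and bootstrap-resampled
training sets (the source of member diversity is unstated); weights ∝
validation macro-F1, soft-voted.

## Synthetic cohorts

The generator reproduces the study's structure: 60/51/17 slides for
Good/Medium/Bad, an 86/42 train/validation split (the stated 8:2 ratio
conflicts with the printed 86/42 counts; the explicit counts win and the
ratio is treated as descriptive), and 22 external microscope-domain images.
Splits are stratified by largest-remainder apportionment (train 40/34/12,
external 10/9/3).

*Feature bags*: per class, patches mix an uninformative N(0, I) background
with a class component N(separation·u_c, I) on fixed orthonormal directions;
the informative fraction per bag is U(0.1, 0.5) — within-slide signal
prevalence is never stated anywhere, so this is a modelling assumption and
an explicit knob. External bags pass through a fixed random affine map
scaled by `domain_shift`. *Images*: white canvases with hematoxylin/eosin-
toned elliptical blobs clustered in a biopsy-like core; blob density and
eccentricity increase Good → Medium → Bad as a cellularity proxy; the
microscope domain adds a 2× downscale/upscale blur and a global hue shift.
None of this claims visual realism — no nuclei rendering, no stain physics,
no pyramidal container — so passing tests demonstrate pipeline correctness
and recoverability of planted signal, not clinical performance.

## Numerical choices and degenerate inputs

- The network and training loop run on a small reverse-mode autodiff core
  written for this package; gradients are finite-difference-verified in the
  test suite. Everything is float64 numpy on CPU, so fixed seeds reproduce
  runs exactly.
- Probabilities are clamped at 1e-12 inside log; sigmoids clip their input
  at ±500. Argmax ties in evaluation and slide aggregation resolve by the
  fixed (Good, Medium, Bad) order.
- A bag with a single patch is valid (cells of size 1); empty-mask slides
  yield empty patch lists and are skipped with a warning at encoding time.
- Heatmaps: attention is scattered on the patch grid, Gaussian-smoothed
  (σ = 1 cell), min-max rescaled per slide (whether the original rescaled
  per slide or globally is unknown); contours are marching-squares level
  sets at threshold 0.5 of the rescaled map ("a defined threshold" is
  unquantified); a constant map cannot be rescaled and is flagged instead.
  Attention, not gradient saliency, is the map source — consistent with the
  architecture; Grad-CAM-style alternatives are out of scope.
- Undefined metric ratios (0/0) report 0 with an `undefined` flag; ROC/PR
  AUCs for a class absent from the truth are reported missing, not 0.

## Problem sizes used by tests and the acceptance script

Unit and property tests use a reduced cohort (24 slides, 64-d bags, 8–16
patches per bag) and a 32-d single-layer model. Parameter-recovery runs use
the full 128-slide cohort with 1024-d bags and the desk-scale model
(embed 64, 4 heads, 2 layers, batch 8, ≤30 epochs, patience 10, five
members). These sizes are the package's desk defaults; the published
hyperparameters remain the config defaults.

## Known limitations

- The stub encoder carries only colour/density statistics; morphology-level
  features require plugging a real pretrained backbone into
  `ProjectedBackbone`.
- Exact self-attention is O(T²) in bag size; gigapixel-scale bags would need
  the linear-attention variants deliberately left out.
- The 140-epoch / 25,000-step / batch-64-vs-grid-{8,16,32} accounting in the
  published recipe cannot be reconciled exactly; the schedule is tied to
  optimizer steps as described above, as this package's own resolution.
- Validation-based early stopping and ensemble weighting reuse the same 42
  validation slides, so validation metrics carry mild selection optimism —
  visible in the no-signal (separation 0) cohort, where best-epoch selection
  sits at the upper edge of the binomial chance band.
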