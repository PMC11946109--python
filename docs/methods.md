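# Methods

## Problem setting

Species recognition in underwater survey imagery is an object-detection
problem with three compounding difficulties: low contrast between fish and a
turbid blue-green background, small object sizes, and a heavily long-tailed
species distribution — a few abundant species dominate the annotations while
most species have only a handful of instances.  `reefdet` implements an
anchor-free single-stage detector whose loss design targets exactly these
difficulties, together with a synthetic scene generator that reproduces the
difficulties at desk scale so every claim is testable on one CPU.

## Detection model

The detector follows the modern CSP single-stage template: a stem plus four
stride-2 stages of C2f blocks (split-transform-concat with `n` serial
bottlenecks, every intermediate output joining the final concatenation), an
SPPF block, a PAN-FPN neck (top-down merge, then bottom-up aggregation, four
fusion blocks), and a decoupled anchor-free head.  At each of 3 scales
(strides 8/16/32) the head predicts `C` class logits and four side-distance
distributions over `reg_max + 1 = 17` integer bins; boxes decode as the
softmax expectation of each distribution times the stride, around the grid
center.  A 640-pixel input yields 8400 prediction locations.

The transformer variant replaces the final backbone stage with a stack of
pre-norm multi-head self-attention blocks over the flattened `h·w` tokens of
the feature map, and each neck fusion block with a 1×1 projection followed
by such a stack.  Positional information enters as a learnable 1-D
embedding: a linear layer maps the normalised token index to a d-vector that
is added on the attention path only, so a block with zeroed attention and
feed-forward sublayers is exactly the identity.  Head count 4, no dropout.

### Parameter budgets and calibration

Published budgets for this model family are parameter counts in millions;
they serve as architecture anchors.  The small/medium/large baselines
(depths 1-2-2-1 / 2-4-4-2 / 3-6-6-3, widths 0.50 / 0.75 / 1.00, channel caps
1024 / 768 / 512) land on 11.23 / 25.98 / 43.79 M for 121 classes, within
0.3% of the printed 11.21 / 25.91 / 43.70 M.  For the depth-rescaled
variants the published description fixes the stage depths (6-12-12-6) but
not the width.  A medium width (0.75) with those depths would give ≈ 40 M,
far above the printed 26.87 M for the no-transformer ablation, so the
committed presets double *all* depths of the large layout (backbone
6-12-12-6, neck 6) and calibrate width once against the printed budgets:
width 0.60 with the 512-channel cap gives 26.76 M (−0.4%); adding the
transformer (6 backbone blocks, neck stacks of depth 3, FFN ratio 3.4) gives
30.48 M vs the printed 30.56 M (−0.25%).  These constants are committed in
`architecture._PRESETS` and asserted by the acceptance suite; they are
calibration targets, not tuned to any behavioural test.

The head's box branch uses 17 bins per side (`4·(reg_max+1)` channels,
`reg_max = 16`); the conventional 64-channel variant differs by < 0.01% in
total parameters.

## Losses

Total objective: `L = α₁·L_cls + α₂·L_dfl + α₃·L_box`, defaults
α₁ = 0.5, α₂ = 1.5, α₃ = 7.5.  The box gain α₃ multiplies the box term in
*all* variants (including Wise-IoU), matching the conventional
cls/dfl/box gain triple.

* **Classification** — binary cross-entropy on per-location, per-class
  logits against the assigner's soft targets.
* **Distribution-focal** — interpolated cross-entropy on the two bins
  bracketing each continuous side distance, averaged over the four sides.
* **Box** — complete-IoU (baseline) or Wise-IoU v3:
  `L_WIoUv1 = (1 − IoU)·exp(d²/(W²+H²)★)` with `d` the center distance and
  `(W, H)` the smallest enclosing box of the pair (a config switch selects
  the literal predicted-box reading); `L_WIoUv3 = κ·L_WIoUv1` with
  `κ = θ/(τ·β^(θ−τ))`, β = 1.8, τ = 3.  The outlier degree θ is the
  detached per-box IoU loss divided by an exponential running mean
  (momentum 0.99, initialised at 1, updated once per batch); a fixed-θ mode
  (θ = 2, the published operating point, giving κ = 1.2 exactly) exists for
  reproducible unit arithmetic.  ★ marks quantities treated as constants
  under differentiation: the normalizer and θ.  κ has a single interior
  maximum at θ = 1/ln β ≈ 1.70 for β = 1.8 and decays for larger θ.

* **Class-aware reweighting** — `w(ns) = (1 − ns/n)/(1 − (ns/n)^η)`,
  η ≥ 1 (default 8).  Identically 1 at η = 1; strictly decreasing in
  `ns/n`; bounded in `(1/η, 1]` with limit `1/η` as `ns/n → 1`.
  Granularity: the BCE is weighted per class column; box and DFL terms per
  assigned target by its ground-truth class's weight; background locations
  are unweighted.  A single-class dataset (`ns = n`, `C = 1`) takes
  `w = 1`; `ns = n` with `C > 1` violates the count invariant and is
  rejected.  The weight function is one small function, swappable if an
  alternative algebra is preferred.

All three terms are normalised by the total assigned target-score mass of
the batch (floored at 1), the convention of this detector family.

## Assignment and training

Task-aligned assignment: candidate locations are grid centers inside a
ground-truth box; each ground truth keeps its top-10 candidates by
`score^0.5 · IoU^6`; a contested location goes to the ground truth with the
higher IoU, ties to the lower index — fully deterministic.  Soft
classification targets are the alignment metric normalised per ground truth
to peak at its best candidate IoU.  Side-distance targets are clamped to
`[0, reg_max − 0.01]`.

Training uses SGD (momentum 0.937, weight decay 5e-4 on conv/linear weights
only), linear warmup (3 epochs) into cosine decay, gradient-norm clipping at
10, batch statistics for batch norm (momentum 0.03, eps 1e-3), and no
pretrained weights or augmentation (mosaic off — synthetic scenes are
already randomised).  One integer seed drives initialisation and data order;
deterministic mode reproduces losses bit-for-bit.  A non-finite loss aborts
with a diagnostic dump of the offending batch.  The whole stack (autodiff,
conv/BN/attention) is implemented in numpy, so desk-scale models train in
seconds to minutes on one CPU; large presets are built for parameter
accounting and shape checks rather than full training.

## Evaluation

Greedy confidence-ordered matching per class and image (highest-IoU
unmatched ground truth at or above the threshold; ties to the lowest GT
index; equal confidences keep file order).  AP integrates the monotone
all-points-interpolated precision-recall envelope (not 11-point).  mAP is
the unweighted class mean at IoU 0.5 and averaged over 0.50:0.05:0.95.
Classes with no ground truth and no detections are excluded from means;
with detections but no ground truth they contribute AP 0.  The stratified
report averages AP within head/middle/tail terciles of ground-truth
frequency.  Inference uses no confidence floor for evaluation (0.001
numerical cutoff), class-wise NMS at IoU 0.7, at most 300 detections per
image.

## Synthetic data: what it does and does not show

The generator emulates the *statistical and visual structure* of long-tailed
underwater survey data, not its appearance: power-law class frequencies
(`p_k ∝ rank^−γ`, every class floored at one instance), fish-like shapes
(rotated ellipse body + triangular tail; species-specific hue, aspect ratio
and striping), low foreground/background contrast (default blend 0.45),
Gaussian blur (σ 0.8 px), and bright particles emulating suspended matter
(density 4·10⁻⁴ per pixel).  Occlusion between instances is capped at IoU
0.3 with bounded placement retries.  Splits are 70/15/15 by image, adjusted
so every generated species appears in training.  Default desk-scale study
conditions: 12 classes, γ = 1.5, 64-pixel scenes, 1–4 instances per scene.

Passing tests on these scenes demonstrate that the losses, assignment,
optimisation and evaluation interact correctly and that class-aware
reweighting helps under controlled imbalance.  They do not demonstrate
performance on real imagery: real fish vary in pose and texture, backgrounds
contain structure (reef, gear), and annotation noise exists.  Species
identity here is carried mostly by colour, which is a far easier cue than
real inter-species differences.

## Problem sizes used by the test suite

Behavioural checks run at deliberately small scale: the overfit sanity check
trains the micro preset (width 0.25, depths 1-1-1-1, 64-pixel input,
~0.9 M parameters) on 8 scenes until mAP_0.5 ≥ 0.95 (typically ~80 epochs);
the imbalance check trains it for 15 epochs on a 215-image 12-species
γ = 1.5 dataset (~150 training images), three seeds per η ∈ {1, 8}, and
compares mean tail-tercile AP_0.5 on the validation split.  These sizes are
the package's chosen desk-scale study conditions; the directional claim
(η = 8 lifts tail AP) is asserted, not any absolute mAP.

## Known limitations

* O(N²) attention memory: transformer presets at 640-pixel inputs are
  buildable (for parameter accounting) but not practical to run forward in
  numpy; tests exercise transformer blocks on small maps.
* Batch-norm statistics from batches of 4–16 are noisy; evaluation uses
  running statistics, so very short runs can show a train/eval gap.
* The evaluator is a from-scratch implementation of the standard matching
  and integration rules; corner-case conventions (e.g. crowd boxes) from
  the reference COCO tooling are out of scope.
* Checkpoints are plain `.npz` weight archives (format version 1); no
  optimizer state is saved, so resumed runs restart momentum.
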