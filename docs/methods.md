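# Methods

This note records the models, conventions and design decisions behind the
package, in enough detail that every number the tests assert can be traced
to a rule stated here.

## 1. The detector family

The baseline is the standard nano-scale anchor-free one-stage detector:
width multiple 0.25 (stem widths 16/32/64/128/256), depth multiple 0.33
(C2f repeats 1/2/2/1 in the backbone, 1 per neck stage), SPPF at P5, a
PAN-FPN neck, and a decoupled head over strides 8/16/32 with
distribution-focal box regression (`reg_max = 16`, so 64 box channels per
scale). With 4 classes it carries 3,011,628 parameters — the same counting
convention applied at 80 classes yields 3,157,200, the published figure for
this architecture, which anchors every convention below.

Three independent switches define the variants:

* **S** replaces SPPF with SPPE at P5;
* **R** replaces every C2f (backbone and neck) with RGE;
* **C** replaces the PAN-FPN neck with the CFFP neck.

Composition is commutative by construction: a variant is a flag triple, not
an application order.

## 2. Block definitions and the calibration of their free widths

The three lightweight blocks are published only as diagrams that omit
widths. The published ablation table, however, fixes whole-model
budgets for all seven variants. We therefore *calibrate*: enumerate a small
discrete design space and keep the configuration whose whole-model budgets
reproduce the published cells (`scrnet.calibration`; re-runnable via
`scrnet calibrate`, ~4 s). The frozen winners:

**SPPE** (`hidden = 4`, three 3×3 convs): a 1×1 ReLU projection of the
256-channel P5 map to 4 channels, one 5×5/s1 max pool (standing in for the
first 3×3 convolution of the ELAN stack), three 3×3 ReLU convolutions, all
five stages tapped, concatenated (20 channels) and expanded back to 256 by
a 1×1 convolution — 7,120 parameters against SPPF's 164,608. The published
whole-model row constrains SPPE to fewer than ~8,400 parameters, which is
what forces the very narrow hidden width; among budget-equivalent ties the
search prefers the deepest conv stack (most ELAN-like), then the widest
hidden channel.

**RGE** (`scale = 25/64`, depthwise cheap ops, C2f-like stream concat):
`cv1` (1×1) produces `2*ch` channels with `ch = round(scale*C_out)`, split
into two streams; one passes through a RepConv; `(n-1)` depthwise 3×3
convolutions chain off it producing duplicate ("ghost") maps; both split
halves, the RepConv output and every ghost map are concatenated
(`(n+2)*ch`) and projected to `C_out`. The nominal scale for such blocks is
0.5, but no enumerated topology reproduces the published `+R` row (2.23 M)
at scale 0.5 — candidates land between 2.13 and 2.59 M; the 1/64-grid
search pins 25/64 ≈ 0.39. `scale` remains an argument with the calibrated
default.

**CFFP**: laterals (1×1, 64 out) on P3/P4/P5; a channel-preserving 1×1
refinement on the P5 stream before the first upsampling; top-down fusion by
C2f (n = 2) — the P4-level fusion at 128 output channels, refined by a
1×1 (128→128) before the second upsampling; a third 1×1 refinement on the
P3 lateral; top-down P3 fusion to 64; then a bottom-up path entirely of 1×1
convolutions (stride-2 1×1 downsampling, 1×1 fusion of each concat pair),
with the head consuming (64, 64, 64). Under `R`, the two top-down C2f
fusions become RGE; the 1×1 convolutions are untouched — which is exactly
why the published C→CR parameter delta (0.57 M) equals the backbone-only
RGE saving.

### Counting conventions (calibrated once, then frozen)

* **Parameters**: conv weights (`C_out·k²·C_in/g`) + bias only where a bias
  exists (head output projections, fused RepConvs) + `2·C_out` BatchNorm
  affine terms. Convolutions followed by BN are bias-free. The fixed DFL
  projection (16 weights) is counted. The textbook formula that gives every
  conv a bias misses the baseline anchor by ~8 k parameters.
* **FLOPs**: `F_h·F_w·C_out·(2·k²·C_in/g + bias)` with (F_h, F_w) the
  *output* map — one multiply plus one add per weight (the convention of
  standard profilers). The literal "(2k²−1) multiply-adds + 1" textbook
  count is available (`convention="macs-1"`) but yields 6.95 G for the
  baseline instead of the published 8.1 G, so the 2-MAC convention is the
  calibrated one. Pooling, activations, upsampling, concat and BN count as
  zero-FLOP layers.
* **Counting graph**: the *training* graph (RepConv branches unfused).
  Deploy-mode counting was tried first in the search and cannot reproduce
  the published table's consistent subset; training-graph counting is also
  what a profiler run on the training model reports.

### What the published table can and cannot support

The SPPF→SPPE swap removes a fixed 157,488 parameters wherever it is
applied, because the P5 widths do not depend on the neck. The published
table shows the swap as −0.16 M between baseline and S *and* between CR and
CRS, but as −0.26 M between C and CS. These cannot all hold; at most one of
the C/CS cells is attainable by any compositional architecture. The search
matches **C** (2.07 M), because the published running text independently
states a 31.9 % parameter reduction for the neck change alone
(3.01·(1−0.319) ≈ 2.05 M ≈ 2.07 M), while nothing independent supports the
CS cell. Our CS then computes to 1.91 M = 2.07 − 0.16 — the value the
table's own deltas imply — and the corresponding acceptance assertions at
the printed 1.81 M / 6.6 G fail by design. The R-variant FLOPs land at
6.06 G (prints 6.1, one rounding step under the published 6.2); all other
cells reproduce exactly.

## 3. Reparameterization

BN with frozen statistics is affine, so `BN(conv(x))` folds into a biased
conv: `W' = W·γ/√(σ²+ε)` per output channel, `b' = β − μ·γ/√(σ²+ε)`.
A RepConv fuses by folding each branch, zero-padding the 1×1 kernel to 3×3,
expressing the identity branch as a BN-folded Dirac kernel, and summing.
The algebra is exact; float32 evaluation stays within 1e-4 max-abs (the
test tolerance; observed ~1e-6 on realistic weight scales) and within 1e-8
when carried out in float64 (verified against an independent nested-loop
convolution oracle). Fusion is idempotent and performed in place; the
training branches are dropped from the parameter registry so that deploy
parameter counts, state dicts and optimizers all see the fused form.
Equivalence is resolution-independent, so verification uses reduced inputs
(64–128 px) to stay within CPU budget.

## 4. Profiling: two independent routes

`profile_model` propagates shapes symbolically (no data touched) using each
block's declared layer list. `profile_by_forward` runs a real forward pass
in which every executed convolution reports its true output size through an
operator hook. The two routes share no shape arithmetic and must agree
within 1 % on every variant (they agree exactly in practice); the
acceptance script refuses to emit numbers if they disagree. Reduction
percentages are computed on the table-rounded M/G values, because that is
how the published percentages (55.5 %, 37.0 %, 5.3 %) were derived.

## 5. Synthetic scenes

The generator emulates shallow-water survey imagery statistically, not
photo-realistically: a blue-green background of low-frequency sinusoids
plus grain, and four shape archetypes (spiky disc, elongated blob,
five-armed star, ribbed fan) with per-class palettes, random scale (6–22 %
of the image side by default), orientation and colour jitter, placed by
rejection sampling under a pairwise IoU cap (0.4). Labels are tight mask
extents, normalised cx/cy/w/h, written with six decimals. Everything
derives from one `numpy` PCG64 seed: same seed, byte-identical scene.

Degradations (hazing = alpha-blend toward a grey-blue airlight, Gaussian
blur, contrast squeeze toward the mean, multiplicative horizontal light
ramp) act on pixels only and never touch labels. Augmentations (horizontal
flip, random crop with boxes re-clipped and dropped below 25 % remaining
area, colour gain jitter) transform boxes consistently.

What a green test on this generator establishes: the pipeline — rendering,
label bookkeeping, geometry, matching, mAP — is correct and deterministic.
What it does not establish: detection performance on real underwater
imagery, whose blur statistics, occlusion patterns and class imbalance the
generator does not model.

## 6. Training smoke

The training components follow the baseline ecosystem defaults (the
published training setup leaves them unspecified): task-aligned assignment (top-k 10,
α = 0.5, β = 6.0, centre-inside candidate rule, IoU tie-breaking, a
nearest-anchor fallback so every ground truth is assigned), composite loss
`0.5·BCE + 7.5·(1−CIoU) + 1.5·DFL` normalised by the summed target scores,
SGD with lr 0.01, momentum 0.937, weight decay 5e-4 (BN/bias exempt) and a
25-step linear warmup — the published optimizer hyperparameters, with
epochs scaled down to an overfit smoke.

The smoke test trains the full model from scratch on 8 synthetic images at
**64×64** input (the documented scaled-down knob relative to the nominal
640; grids 8/4/2, 84 anchors) and requires train-set mAP@0.5 ≥ 0.9 within
300 full-batch steps; it typically reaches 1.0 around step 150 in ~1 min of
CPU. The other six variants are exercised by 12-step loss-descent checks,
which verify gradient flow through every block type at a fraction of the
cost. Divergence (loss > 10× initial) and non-finite losses abort with
explicit errors. Determinism: single NumPy seed, full-batch steps,
single-algorithm kernels — two runs with the same seed produce bit-identical
losses on the same machine.

## 7. Evaluation conventions

Greedy one-to-one matching in descending confidence at IoU ≥ 0.5 per class;
AP by all-point interpolation over the monotone precision envelope (the
convention of the surrounding ecosystem, chosen over 11-point sampling
because the definition is a plain integral); mAP the unweighted mean over
classes that have ground truth (classes without ground truth are flagged
and excluded, never counted as zero). Evaluation decodes with confidence
threshold 0.001 and NMS IoU 0.7 (mAP mode); display mode uses 0.25/0.45.
TN is carried in the confusion counts for completeness but enters no
metric. Speed is the plain arithmetic mean of per-image seconds; no speed
claim participates in any assertion because it is hardware-bound.

## 8. Known limitations

* Pure-NumPy training is ~2 orders of magnitude slower than a GPU
  framework; the training surface is a smoke test, not a training system.
* The calibrated SPPE width (4 channels) is what the published budgets
  force, but a 4-channel bottleneck on a 256-channel map is a severe
  representational constriction; we make no claim that it reproduces the
  published *accuracy*, only the published budgets.
* FLOP figures follow the 2-MAC profiler convention; hardware-level
  operation counts differ.
* `scenes_to_batch` letterboxes per image; mosaic augmentation and
  multi-scale training are not implemented (the smoke deliberately runs
  without them).
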