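# Methods

`pigletdet` implements a lightweight single-stage detector for locating and
counting pre-weaning piglets in farrowing-crate imagery, in the MGDT-YOLO
family of YOLOv8n derivatives: a backbone whose C2f blocks are replaced by a
multi-scale spatial pyramid attention block (MSPA C2f), a gather-and-
distribute (GD) neck with ConvNeXt-V2 fusion that produces a single fused
map, one task-aligned detection head, and a sample assigner whose
classification exponent decays over training.  This note records the model,
the choices made where the design was genuinely open, and what the tests do
and do not establish.

## Numerical substrate

The network, its gradients and the training loop run on a compact
reverse-mode automatic-differentiation engine over NumPy arrays
(`pigletdet.nn`).  Convolution is computed as one einsum per kernel tap
(grouped and depthwise variants included); modulated deformable convolution
is composed from a coordinate-differentiable bilinear sampler, a sigmoid
gate and a 1×1 contraction, so its gradients — including those with respect
to the predicted offsets — follow from the primitive set.  Every primitive
is verified against central-difference numerical gradients in the test
suite.  Layers compute in float32; gradient-checking tests feed float64.
Forward passes of identical weights can differ at the level of float32
reduction order across BLAS thread schedules, which is why equality
assertions on scores use a 1e-5 tolerance.

## The MSPA C2f block

The block splits its C input channels into three contiguous chunks
(remainder channels to the earliest chunks, so widths differ by at most
one).  The hierarchy is F̂₁ = Conv₁(F₁), F̂₂ = Conv₂(F̂₁ ⊕ F₂),
F̂₃ = Bottleneck(F̂₂ ⊕ F₃), with ⊕ element-wise summation; per branch a
5ω-descriptor (global mean plus flattened 2×2 adaptive average pooling,
channel-major then row-major order) passes through a bottlenecked two-layer
gate (ReLU, then sigmoid); a softmax across the three chunks, per channel,
yields weights that rescale the branches before the concatenation and the
1×1 aggregation Conv₃.

The published description leaves several internals open.  They were
resolved *once* by enumerating the small discrete configuration space
(chunk rule front-heavy vs ceil; 1×1 convolutions with batch-norm vs bias;
bottleneck expansion 0.25/0.5/1.0, one or two conv pairs; gate hidden width
⌊5ω/r⌋ for r in 1..32, biased or not, shared across chunks or per-chunk;
output width 64 or 128) against the published parameter counts of the
block comparison — 107.264 K for the standard C2f and 14.402 K for the MSPA
block at 64 in / 128 out.  The standard C2f resolves to the ordinary
YOLOv8 block with one bottleneck; the MSPA side has a **unique** solution:

* front-heavy chunking (22, 21, 21);
* Conv₁/Conv₂/Conv₃ as biased 1×1 convolutions without normalisation or
  activation (they are linear maps);
* bottleneck expansion 0.25 (hidden width ⌊0.25ω⌋) with batch-norm + SiLU
  and a residual connection;
* one channel-interaction gate shared across the three branches, hidden
  width ⌊5ω/4⌋, biased projections.

`pigletdet.accounting.resolve_comparison_config` re-runs this enumeration
and cross-checks it against instantiated modules; the acceptance script
reports the resulting count.  Because the chunk-wise softmax needs equal
branch widths, block input widths must satisfy C mod 3 ≠ 2; the default
backbone widths (48, 96, 144, 192) all divide by 3.  Attention weights are
applied to the branches *before* Conv₃ aggregation; an after-aggregation
variant does not typecheck for general widths (the weights have branch
width ω, the aggregated map C_out), so only the former is implemented.  No
residual wraps the whole block beyond the bottleneck's internal one.

## Gather-and-Distribute neck

B2, B3 and B4 are gathered locally at B3's size (stride 8): B2
average-pooled, B4 bilinearly up-sampled (half-pixel centres), B3 through a
1×1 convolution, concatenated and projected.  All four levels are aligned
to B4's size (stride 16, the reference the original gather-distribute
design uses for its low stage), concatenated, fused by a 1×1 convolution
and refined by two ConvNeXt-V2 blocks (7×7 depthwise convolution → layer
normalisation over channels → 4× MLP with GELU and global response
normalisation → projection, residual).  GRN's affine terms start at zero,
so fresh blocks are identities.  The injection module resamples the global
feature to the local size — average pooling when strictly larger, bilinear
interpolation when smaller, identity when equal — and combines a
sigmoid-gated product with a residual copy, refined by one terminal
ConvNeXt-V2 block.  The fused map F_GD therefore lives at stride 8, chosen
because piglets are mid/small objects at 640-pixel inputs; the stride is
configuration-visible, not hard-wired.

The head and neck widths are not printed in the source material; the only
global constraint is the whole-model total of 1.249 M parameters, treated
as calibration.  With backbone widths (48, 96, 144, 192), local width 72
and fused width 86 the assembled detector has 1,248,584 parameters (−0.03%).

## Task-aligned head

A stack of two modulated deformable convolution units (DCNv2 + batch-norm +
SiLU) forms the shared extractor; offset and mask producers are
zero-initialised so training starts exactly at the masked standard-
convolution point (gate sigmoid(0) = 0.5), a property the tests pin down.
Per task (classification, regression), layer attention — globally pooled
stack features through a bottlenecked projection and sigmoid, one gate per
stack layer — mixes the stack, and a further deformable convolution refines
the mixture.  Boxes use distribution-focal parameterisation with
reg_max = 16 (inherited from the YOLOv8 baseline; the redesign alters
structure, not parameterisation): per anchor and side, a categorical
distribution over 17 bins whose softmax expectation is the side distance in
stride units, making decoded extents non-negative by construction.  The
classification bias starts at −4 so the initial loss is not dominated by
the dense negative background.

## Assignment and loss

Candidate anchors are those whose centre lies strictly inside a ground
truth.  The alignment metric is t = s^α · u₊^β with s the predicted score
of the ground-truth class, u the complete IoU (CIoU) between predicted box
and ground truth clamped at zero (a fractional power of a negative base is
undefined; clamping preserves the metric on its valid domain), β = 6 and
top-k = 10 (baseline defaults; never printed in the source).  α follows

    α(epoch) = default_alpha · (max_epochs − epoch) / max_epochs,

default_alpha = 0.5, evaluated once per epoch with epoch indices
0..max_epochs−1 during training, so α approaches but never reaches zero
mid-run; the α = 0 endpoint is exercised analytically in tests.  Per ground
truth, the k candidates with the largest t are positives; an anchor claimed
by several ground truths goes to the larger t, ties to the lower index.
The loss keeps the baseline composite form — binary cross-entropy with
t-scaled soft targets, CIoU box loss, and a distribution-focal term over
the two bins bracketing each true side distance — with weights
(0.5, 7.5, 1.5); the aspect-ratio coefficient of CIoU is treated as a
constant during differentiation, the standard practice.  A batch without
positives degrades to a classification-only loss.

## Synthetic scenes

The generator emulates the statistical structure of farrowing-crate
footage, not its appearance: a textured slatted floor; class-0 piglets as
rotated textured ellipses (body semi-axis 9% of the canvas) placed around a
cluster centre with a tightness parameter; at most one class-1 piglet,
partially emerged at a fixed sow-rear band near the top of the frame;
crate-bar stripes drawn over the piglets in 91% of scenes; saturated
overexposure patches in 11% — both frequencies taken from the composition
reported for the real 2,221-image dataset.  Class-0 counts follow a
truncated Poisson with mean 6 on {0..14}, matching the reported average of
6 piglets per image.  The probability that a scene contains a class-1
piglet is not derivable from the published composition tables; 0.5 is used
as a neutral default and is a parameter.  Boxes are tight to *visible*
extents after occlusion by default; an amodal (full-body) mode exists
because the real dataset's annotation convention is unstated.  Everything
is deterministic given the seed; datasets regenerate byte-identically.

Passing tests on these scenes demonstrates that the mechanism — feature
extraction, fusion, assignment, losses, decoding, counting — is correct
and trainable end to end.  They say nothing about accuracy on real piglet
imagery, which requires the unreleased dataset and GPU-scale training; the
published real-data accuracy tables are explicitly out of scope.

## Problem sizes and numerical choices

The end-to-end check trains a narrow model (backbone widths 12/24/36/48,
fused width 24) on twenty 128-pixel scenes for 150 epochs with Adam at
3e-3 (batch 10), reaching training-set mAP0.5 ≥ 0.90; these sizes keep the
whole suite comfortable on a single CPU while still exercising every
module jointly.  Full-scale defaults follow the published recipe: 100
epochs, batch 16, learning rate 1e-3 (SGD with momentum 0.9 and a 3-epoch
linear warmup; the source does not name its optimiser), IoU threshold 0.5.
The counting confidence cutoff defaults to 0.25 (not printed in the
source).  Images with zero ground-truth count for a class are excluded from
that class's MAR average — the only division-safe reading of the metric —
and kept in MAE/MSE.  NMS breaks score ties by original detection order;
greedy metric matching prefers higher IoU, then the earlier ground-truth
index.  MAC counting uses one multiply-accumulate per kernel weight per
output position plus 2 operations per element for normalisation and
activation layers; the published per-block MFLOPs figures are not exactly
recoverable under any single per-element overhead convention consistent
across both blocks, so the convention is reported alongside every count
rather than calibrated to the table.

## Known limitations

* Piglets are schematic ellipses; no pose, contact deformation, motion
  blur or camera noise.  Detection difficulty is far below real footage.
* Batch normalisation uses per-batch statistics; very small batches at
  full width can be noisy (the miniature configurations used in tests are
  unaffected at batch ≥ 4).
* The engine is CPU-only and optimised for clarity; wall-clock performance
  and the published inference-time/deployment results are out of scope.
* The FAM reference level, IFM/TIM widths and extractor depth are
  documented defaults, not claims about the original implementation.
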