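# Methods

## Problem and model family

The package targets single-fruit surface-defect classification: RGB images of
individual jujubes, one of six classes (deformed, wrinkled, cracked, moldy,
bird-pecked, normal), nominally 224×224. Two classifiers share one skeleton:

* **ConvNeXt-Tiny reference.** Patchify stem (4×4 convolution, stride 4,
  3→96 channels, channel LayerNorm), four stages of residual blocks with
  depths (3, 3, 9, 3) and widths (96, 192, 384, 768), LayerNorm + 2×2/2
  convolution downsamples between stages, global average pooling, LayerNorm,
  linear head. Each block computes
  `x + drop_path(γ ⊙ W₂ GELU(W₁ LN(dwconv₇ₓ₇(x))))` with a 4× MLP expansion
  and a learned per-channel scale γ initialized at 1e-6.
* **Lightweight two-branch network ("JujubeNet").** Every ConvNeXt block is
  replaced by an MDC block, and CBAM attention modules are inserted after the
  stem and after each of the three downsamples (scheme c; schemes a/b and
  "none" are constructible for ablation counting).

### The MDC block and its calibration

The MDC block splits its C input channels into two disjoint halves of width
c = C/2. Branch A applies the ConvNeXt design at width c. Branch B applies a
channel LayerNorm, then two consecutive depthwise convolutions (wide-residual
style), each followed by GELU, then a per-channel scale. The branch outputs
are concatenated back to C channels, passed through drop path, and added to
the block input.

Three micro-architectural choices are not determined by the block diagram:
the branch-A MLP expansion {2, 4}, the branch-B depthwise kernel {3, 5, 7},
and the placement of a 1×1 channel-mixing convolution in branch B
{after each depthwise conv, once at the end, none}. The package treats this
2×3×3 grid as an enumerable candidate family and **calibrates** it against
the printed ablation parameter counts: build the full network with and
without CBAM for each candidate and pick the one minimizing the summed
deviation from 8.5 M / 8.4 M, requiring agreement within 0.15 M. The unique
winner is expansion 4, kernel 5, no pointwise convolution, giving exactly
8,505,756 and 8,405,910 trainable parameters (8.5/8.4 M at one decimal,
30.6 % of the 27,824,742-parameter ConvNeXt-Tiny). Channel splitting (rather
than duplicating the full input into both branches) is forced by the same
arithmetic: duplication needs entry projections whose parameters are
incompatible with the printed counts.

### CBAM

Channel attention: `M_c(F) = σ(MLP(avgpool(F)) + MLP(maxpool(F)))` with a
shared bottleneck C → C/r → C (ReLU between, biases included, r = 16).
Spatial attention: `M_s(F) = σ(conv₇ₓ₇([mean_c(F); max_c(F)]))`. Applied
sequentially, `F′ = M_c(F) ⊗ F`, `F″ = M_s(F′) ⊗ F′`. Both gates lie
strictly in (0, 1), so `|F″| ≤ |F|` elementwise, and with all attention
parameters zero both gates are exactly 0.5, giving `F″ = 0.25·F` — both
properties are asserted in tests. This formulation reproduces the printed
+0.1 M parameter increments (27.8→27.9 M and 8.4→8.5 M) exactly (99,846
parameters at widths 96…768), which is also why the stem counts as a
"downsample" for scheme c: four insertions, not three.

## Numerical core

No GPU tensor framework is used: the package runs on a compact NumPy
reverse-mode autograd core (`jujubenet.nn`) purpose-built for these
networks — grouped/depthwise convolution via strided patch views and einsum,
positionwise linear maps, channel LayerNorm, exact (erf-based) GELU,
sigmoid, pooling reductions, a fused softmax cross-entropy, and stochastic
depth. Gradients of every primitive are finite-difference checked; block
forwards are additionally verified against independent per-position loop
oracles in float64 (≤1e-5 relative). All arithmetic is float32; weights are
initialized from a truncated normal (σ = 0.02, clipped at 2σ) with zero
biases, and per-branch layer scales start at 1e-6 (exposed as 0 for
identity tests).

Drop path follows the usual stochastic-depth convention: a residual branch
is zeroed per sample with probability p during training and survivors are
rescaled by 1/(1−p); per-block rates ramp linearly from 0 to 0.1 across the
18 blocks. Evaluation mode is exactly deterministic.

## Parameter and FLOPS accounting

The printed comparison tables quote "FLOPS(G)" figures that equal per-image
GMACs × 32 (a batch factor): VGG-16 15.47×32 ≈ 495, ResNet-18 1.81×32 ≈ 58,
ResNet-50 4.09×32 ≈ 131. The package adopts that convention and reports the
per-image MAC count alongside. MACs are counted for convolutions
(k²·C_in/g·C_out per output position) and linear maps; normalization,
activation and pooling are not counted, and window-attention matmuls in the
Swin description are listed as uncounted rather than silently dropped —
MAC totals therefore agree with common counting tools to ~1 %, and only
parameter counts are treated as exact.

Baselines (ResNet-18/34/50, DenseNet-121, Swin-Tiny, VGG-16,
SqueezeNet-1.1) are counted from analytic layer-by-layer descriptions of
the canonical architectures with the head resized to 6 classes; each
description reproduces the published 1000-class total exactly (e.g.
ResNet-18 11,689,512; Swin-Tiny 28,288,354). Known table quirks are
documented, not targeted: the printed VGG-16 row (138.4 M) corresponds to a
1000-class head (6-class is 134.3 M), printed SqueezeNet 0.8 M does not
match a 6-class SqueezeNet (≈0.73 M), and the printed Swin-Tiny 39.2 G is
inconsistent with the ×32 convention.

## Synthetic corpus

Real acquisition-platform data is emulated procedurally: a shaded red-brown
ellipse with pose/scale/hue jitter on a dark textured background, plus one
defect signature per class (radial boundary dents; sinusoidal luminance
ridges; a dark random-walk polyline; gray-green Gaussian blotches; a dark
near-circular excision at the fruit edge). Every image is a pure function
of (class, base id, seed), so corpora rebuild byte-identically.

Each of the 6·n base images yields itself plus one image per enhancement
method — Gaussian noise (σ = 8 intensity levels), random crop (70–95 % per
dimension, resized back), hybrid photometric jitter
(contrast/brightness/saturation ∈ [0.8, 1.2]), and a horizontal-or-vertical
flip — the 5× factor that turns 12,000 base images into the 60,000-record
corpus. Splits are assigned at base-image level, stratified per class,
exactly 7:2:1 (hence n per class must be a multiple of 10); all five
records of a base inherit its split, so augmented near-duplicates can never
leak across splits. At n = 2000 per class this yields 42,000/12,000/6,000
records.

What the generator does **not** emulate: real jujube texture statistics,
specular/lighting variation of the conveyor platform, intra-class defect
diversity, or ambiguous multi-defect fruit. Passing tests therefore
demonstrate that the pipeline is correct and that the architecture can fit
and discriminate visually separable classes — not that the published
accuracies transfer to real data.

## Training protocol

AdamW (β = 0.9/0.999, decoupled weight decay 0.05 applied only to rank-≥2
weights), cross-entropy loss, batch size 32. The learning rate is updated
every iteration: 2 warm-up epochs linearly from lr_init/100 to
lr_init = 5e-4, then cosine annealing to lr_min = 5e-5. The cosine is
parameterized over t/(T−1) so the final iteration lands exactly on lr_min
(and the warm-up end exactly on lr_init); the midpoint value is
lr_min + (lr_init−lr_min)/2 = 2.75e-4. Default 300 epochs; the CPU test
harness runs reduced configurations instead (depths (1, 1, 2, 1), widths
(24, 48, 96, 192), attention reduction 8, 64×64 inputs, 60 bases per
class, 15 epochs), where the network must overfit its 1,260-image training
split to ≥95 % accuracy. Augmentation is frozen on disk (the corpus is a
fixed artifact); online re-sampling exists as an explicit non-default.
Per-channel input standardization uses training-split statistics, recorded
in the training history. Validation accuracy is measured at each epoch end;
best-validation and last checkpoints are kept.

## Evaluation and saliency

Multiclass accuracy is trace/total of the confusion matrix; per class,
recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN). Summary
values are macro averages — on a class-balanced set macro recall equals
accuracy exactly, matching the accuracy==recall pattern of the printed
tables. Zero-denominator cases score 0 and are flagged rather than raising.

Grad-CAM: for a chosen spatial layer (stem or any stage output; default the
deepest, stage 4), weights α_k are spatial means of ∂logit_c/∂A_k; the map
is ReLU(Σ α_k A_k), bilinearly upsampled to the input and min–max
normalized to [0, 1]. All-zero maps are returned as zero with a degeneracy
flag. Overlays blend a linear blue→red colormap with configurable opacity.

## Design choices on genuinely open points

* Drop path acts on the concatenated two-branch output (as described), not
  per sub-branch.
* Scheme c places the first CBAM immediately after the stem normalization.
* Branch-B normalization appears once at branch entry; GELU follows each
  depthwise convolution.
* Random crop re-resizes to the original size (keeps the corpus
  size-uniform) rather than padding.
* Rounding of "millions" is half-away-from-zero to one decimal, as in the
  printed tables.

## Known limitations

* The autograd core is single-threaded NumPy; it is meant for desk-scale
  verification, not 300-epoch 224×224 training.
* MAC totals depend on counting conventions (±1 %); only parameter counts
  are exact.
* The calibrated MDC wiring is the unique member of the enumerated family
  consistent with the printed counts, but wirings outside that family
  cannot be excluded.
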