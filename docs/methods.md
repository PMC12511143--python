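# Methods

## Scope and model

`giwtnet` implements a lightweight single-stage detector for bark-beetle
(Scolytinae) trap imagery built from three architectural ideas on a
YOLOv11-small-style backbone/neck/head:

1. **GIConv** — a ghost-inception downsampling convolution. Half the output
   width (n/2 channels) comes from a primary k×k strided convolution (the
   "core" map); the other half from a four-branch multi-scale mixer applied
   to the core map (1×1; 1×1→3×3; 1×1→3×3→3×3; 3×3-max-pool→1×1, each
   producing c/4 channels at c = n/2). Per output pixel the mixer costs
   (1/4 + 13/32 + 31/32 + 1/4) c² = (15/8) c² multiply–accumulates, so the
   full module costs H·W·(n/2)·k²·c_in + (15/8)·H·W·(n/2)² against
   H·W·n·k²·c_in for a standard convolution — the ratio
   S = 1/2 + 15n/(32 k² c_in) ≈ 0.604 at k = 3, n = 2c.
2. **WTConv (wavelet-transform convolution)** inside the C3k2 bottlenecks
   (C3K2_WT). An orthonormal 2-D Haar analysis splits the map into LL/LH/HL/HH
   subbands at half resolution; small depthwise kernels act jointly on the
   four bands of successively deeper low-frequency maps; synthesis transforms
   recompose the output, plus a full-resolution depthwise base path. A k×k
   kernel at level L spans 2^L(k−1)+1 input pixels, so the receptive field
   doubles per level while parameters grow by a constant
   4·C·k² + 4·C per level.
3. **Squeeze-excitation gates** on each exported scale (P3/P4/P5, strides
   8/16/32) between neck and head: global average pool, c→c/r bottleneck with
   SiLU, c/r→c with sigmoid, per-channel rescale (r = 16 by default; a
   backbone placement variant exists behind `se_placement`).

The head is anchor-free: per cell, class logits (6 classes) and four side
distances in distribution-focal form (16 bins per side, in stride units),
decoded by softmax expectation.

## Compute core

All forward/backward computation runs on a small NumPy reverse-mode autograd
engine written for this package (`giwtnet.autograd`): strided/grouped
convolution via sliding-window views and BLAS contractions, max-pooling,
nearest upsampling, batch normalisation composed from primitives, batched
matmul attention, and numerically-stable loss primitives. The engine also
hosts the multiply–accumulate counter used by the instrumented cost checks
(conv and linear MACs only; normalisation, activations and pooling excluded;
GFLOPs = 2 × MACs). The Haar analysis/synthesis pair is implemented directly
from the 2×2 butterfly; because the transform is orthogonal its adjoint *is*
its inverse, which makes the backward pass exact by construction.

## Conventions pinned by the printed layer table

Convolutions are bias-free with per-channel batch normalisation (2 learnable
parameters per channel) and SiLU. That convention is forced by the stem row
(3·32·9 + 2·32 = 928) and reproduces every derivable row exactly:
GIConv stages 11 296 / 81 728 / 326 272 / 713 984 (which also pins the stage
channel plan 32→64, 128→128, 256→256, 256→512), SPPF 656 896, and C2PSA
990 976. The four printed C3K2_WT rows (26 080 / 103 360 / 293 632 /
1 127 936) are **not** reproducible from any stated wavelet configuration;
`blocks.calibrate_wtconv_config` enumerates kernel size {3,5,7} × levels
{1,2,3} × replacement pattern × scale on/off and reports every candidate's
deviations instead of adopting a guess (closest: k = 5, L = 1, both
bottleneck convolutions replaced — stage 1 gives 25 216 vs 26 080). The
package default is therefore k = 5, one level, base path on, both convs
replaced, all exposed in `NetworkSpec`.

Other numerical choices: channel counts must be divisible by 8 (no silent
rounding); the concatenation order is core map first, then mixer branches;
inception-internal convolutions are stride 1 (the primary conv carries the
stride); per-channel WTConv scales start at 1 and kernels use fan-in uniform
initialisation; odd inputs to the wavelet transform are edge-replicated to
even size and cropped back after synthesis, preserving exact reconstruction.

The reference table's spatial column corresponds to a 320×320 input (stem
160×160 … deepest 10×10) while training resizes to 640×640; spatial sizes
here are parameterised by input size, so the table comparison runs at 320 and
training can use any multiple of 32. Total parameters of the assembled model
are 8 536 714 and 20.7 GFLOPs at 640² — close to, but deliberately not
asserted against, the printed 8.4 M / 18.7 G, which the wavelet-stage
ambiguity makes unreachable; the comparison utility reports deviations
instead.

## Evaluation

Matching is class-wise greedy over descending confidence with one match per
ground truth. AP uses 101-point interpolation of the precision envelope
(exact all-point integration behind a flag); mAP@50~95 averages the
class-mean AP over IoU 0.50…0.95 step 0.05. Reported P/R/F1 use confidence
0.25 and per-class NMS IoU 0.45; the AP operating point is confidence 0.001
and NMS IoU 0.7. 0/0 ratios are defined as 0. Internally everything is a
fraction; percent formatting with one decimal happens only at the reporting
boundary. Classes with no ground truth are excluded from class means and
logged. True-negative-based metrics are out of scope.

## Training

SGD with momentum 0.937, weight decay 5e-4, batch size 32, 300 epochs,
initial learning rate 0.01 under cosine annealing to a floor of 1% of the
initial rate; linear warmup ramps the rate over the first 3 epochs at
iteration granularity, so the epoch-level schedule still starts exactly at
0.01. Early stopping monitors validation loss with strict improvement and
patience 100 (a fitness blend, 0.1·mAP@50 + 0.9·mAP@50~95, is available via
`early_stop_metric="fitness"`). Losses: CIoU (box), binary cross-entropy
(class), distribution-focal (side histograms), weighted 7.5 / 0.5 / 1.5.
The assigner routes each ground truth to one scale by its longest side
(< input/8 → P3, < input/4 → P4, else P5) and marks cells whose centres lie
inside the box within 1.5 cells of the box centre. Mosaic (p = 1.0) and
mixup (p = 0.15, λ ∼ U(0.3, 0.7), box union with source weights) are applied
at train time; mixup box weights are carried on the sample but not used to
reweight the loss.

## Synthetic data

The generator emulates the statistical structure of the trap-tray dataset,
not beetle appearance: six classes with hue/stripe-frequency/elongation
prototypes, a bimodal size mix (small 2–6% vs large 10–25% of the image
side, `size_mix` fraction small), a confusability knob that interpolates
class prototypes toward their mean, mottled backgrounds with illumination
gradients, and per-image illumination gain drawn from U(0.6, 1.4) when a
dataset is materialised. Objects are oriented ellipses; boxes are their
exact axis-aligned hulls; placement retries are bounded and near-total
overlap (> 70% of a new box) is rejected. Annotations are Pascal-VOC XML
(1-based inclusive integer coordinates); images are lossless PNG. Dataset
defaults are 64/8/8 images, the desk-scale analogue of the source's
1693/245/245 split.

What passing tests on this data do **not** show: robustness to real
backgrounds, occlusion, clutter, or genuine inter-species appearance; the
generator's value is that every pipeline stage (generation → VOC I/O →
training → evaluation) is exercised end to end with exact ground truth.

## Problem sizes used by the test suite

The unit suite runs blocks at 8–16 px feature maps and the full assembly at
width 0.5 for the parameter table (construction only, sub-second) and width
0.25 for forward passes. The learnability check trains the width-0.25 model
on 8 scenes with three large-regime objects each at 256², batch 4, for at
most 300 iterations (it typically reaches train-set mAP@50 ≥ 0.5 after about
100), with mosaic/mixup off since the aim is an overfitting smoke of the full
gradient path rather than a generalisation benchmark.

## Known limitations

- The C3K2_WT parameter rows and hence the exact published totals are not
  reproducible (see calibration above); totals are reported with deviations.
- The trainer is CPU-scale: it demonstrates learnability and pipeline
  correctness, not the published accuracy, which requires the original
  dataset and GPU-scale training and is explicitly out of scope.
- The task-aligned assigner of the baseline family is replaced by the
  simpler centre-prior rule; this is sufficient for overfitting smoke tests
  but will underperform one-to-many aligned assignment at scale.
- Nearest-neighbour resize is used for image preprocessing; no letterboxing
  (the synthetic scenes are square).
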