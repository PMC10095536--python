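# Methods

## Problem setting

Input images are 8-bit RGB smear photographs; ground truth is an integer
label per pixel with 0 = background (including red blood cells) and 1–5
the five leukocyte types. All metrics derive from the K×K pixel
confusion matrix with rows = truth and columns = prediction.

## Image enhancement (AHE-Retinex)

The correction runs in two stages, applied once per image before
training (not per batch):

1. The image is converted RGB→HSV (all channels scaled to [0, 1], hue as
   angle/360°) and the value channel is equalized with contrast-limited
   adaptive histogram equalization. The clip limit is expressed in the
   normalized [0, 1] convention (default 0.01) with an 8×8 tile grid;
   both are configurable in `RetinexConfig`.
2. After conversion back to RGB, each channel receives MSRCR. The
   single-scale retinex of a channel is
   `R(x,y) = log(I+1) − log((F_σ∗I)+1)`; the +1 offset on 8-bit
   intensities guards `log 0`. The Gaussian surround is normalized to
   sum 1, truncated at 3σ, and applied separably with reflective border
   handling (identical to full 2-D convolution of the outer-product
   kernel, and free of the dark halos that zero padding causes at
   edges). MSR uses scales (15, 80, 250) with equal weights — standard
   MSRCR practice; the source method leaves the scale set open. The
   colour-restoration gain is `c_i = α·log(β·S_i/Σ_j S_j)` with α = 46,
   β = 125; a small relative epsilon keeps all-zero pixels finite while
   leaving the equal-channel case exact. The restored product is
   stretched per channel to [0, 255] between its 1st and 99th
   percentiles.

Where to apply MSRCR is genuinely ambiguous in the literature this
follows (HSV channels vs RGB): hue is angular, so a log-ratio gain on it
is ill-defined; we apply CLAHE on V and MSRCR on RGB.

## Network

U-net with the VGG16 convolution stack as the contracting path (widths
64·m for `base_width` m/64: 64-128-256-512-512, conv counts 2-2-3-3-3,
2×2 max pooling). The four pre-pool encoder maps each pass through an
independent CBAM before channel-concatenation with the decoder:

* channel attention: global average and max pooling over space, one
  shared two-layer MLP (bottleneck C/r, ReLU; r = 16 by default),
  element-wise sum, sigmoid;
* spatial attention: per-pixel channel mean and max, stacked and
  convolved 7×7 to one channel, sigmoid.

Both gates are strictly inside (0, 1), so CBAM attenuates and never
amplifies. The decoder mirrors the encoder (512-256-128-64 at full
width) with bilinear ×2 upsampling followed by two 3×3 convolutions per
stage (transpose convolution is deliberately avoided — checkerboard
artifacts); the head is a 1×1 convolution and per-pixel softmax. Inputs
are scaled to [0, 1]; spatial size must be divisible by 16.

The network, losses and optimizer run on `leukoseg.nn`, a compact
reverse-mode autodiff core over numpy (im2col convolution, argmax-routed
pooling gradients, dense separable bilinear interpolation matrices).
Every backward rule is verified against central finite differences in
the test suite; all computation is float64 and bit-deterministic, which
is what makes the freeze-contract and reproducibility tests exact.

Weights are He-initialized from a seeded generator. Pretrained encoder
weights can be loaded from an .npz archive via
`ModelConfig(pretrained=True, pretrained_path=...)`; random
initialization is the default so nothing is ever downloaded.

## Loss

`L = L_dice + L_focal` (unweighted sum; weights configurable).

* Focal: `−(1−p_t)^γ log p_t` averaged over pixels and batch, γ = 2,
  with `p_t` clamped to [1e-7, 1−1e-7]. γ = 0 recovers cross-entropy.
* Dice: soft counts per class k — `TP = Σ p_k·[y=k]`,
  `FP = Σ p_k·[y≠k]`, `FN = Σ (1−p_k)·[y=k]` — combined as
  `(2TP+s)/(FP+2TP+FN+s)` with smoothing s = 1e-6, averaged over all K
  classes by default (foreground-only via `dice_class_set`). On one-hot
  predictions this reduces exactly to the hard-count form.

## Metrics

Per class (one-vs-rest): P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R),
IoU = TP/(FP+TP+FN); accuracy = trace/total; mIoU = mean per-class IoU.
On hard counts IoU = F1/(2−F1) exactly, and F1 lies between P and R —
both identities are asserted on random matrices. A 0/0 ratio (class
absent from both masks) is reported as NaN and excluded from the mIoU
average instead of being counted as zero, which would punish absent
classes. Core functions return fractions; `MetricsReport` renders
percentages. mIoU includes the background class by default; the CLI
exposes `--foreground-only`.

## Training pipeline

Defaults follow the study conditions: 9:1 split (⌈0.9n⌉ train), batch
size 2, Adam at 1e-4 (no decay — none is specified for the source
schedule), 50 epochs with the encoder frozen followed by 50 with all
parameters trainable. The optimizer is created over the non-encoder
parameters first and its moment estimates persist per parameter across
the phase switch, so decoder momentum is not reset at unfreezing and
frozen encoder weights stay bit-identical through phase 1. Validation
mIoU is recorded every epoch; a NaN loss aborts with a diagnostic.
Checkpoints are .npz weight archives with a JSON sidecar carrying the
model configuration.

## Synthetic data

The generator emulates the *structure* of stained smears — uneven pale
background with a smooth illumination gradient, pale-red RBC distractors
whose colour is deliberately close to leukocyte cytoplasm, and five
phenotypes told apart by nucleus geometry (2–5 joined lobes; two lobes
plus dispersed reddish granules; granule-obscured; kidney-shaped;
round). Cells are drawn on a 2× supersampled canvas (anti-aliased
boundaries); the mask is the per-block majority label, so masks and
images are aligned by construction. Leukocytes never overlap (bounded
retries, then an error); default single-cell tiles are 256×256, matching
the single-cell source images the stitching workflow assumes, and
`stitch_tiles` composes 2×2/3×3/4×4 grids onto 512×512.

What it does **not** model: staining chemistry and its variability,
cell-boundary texture, focus blur, overlapping or deformed cells,
platelets. Passing tests therefore demonstrate that the pipeline's
machinery is correct and can learn colour/shape-separable classes; they
do not certify accuracy on real smears.

The "easy task" (`make_easy_task`) is a 4-class variant — three
distinctly coloured blob classes on a pale background, no distractors,
mild noise — used wherever a CPU-scale run must demonstrably learn.

## Scaled-down experiment sizes

Full-scale training (512×512, width-64 VGG16, 100 epochs) is a GPU-scale
job. The package's learning checks instead train `base_width=8` at
64×64 on 32 images for 2+2 epochs at batch size 1 (128 steps) with Adam
at 3e-3 — a learning rate chosen for a four-epoch run; the 1e-4 default
remains the full-scale condition. Under these conditions the trained
network's held-out mIoU averages well above 0.5 over three seeds while
the untrained network sits near the all-background baseline.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; it is meant for
  correctness, tests and small experiments, not production training.
* CLAHE is delegated to scikit-image; its tile interpolation details
  differ slightly from other implementations, so enhanced pixels are
  reproducible within this package but not bit-identical across
  libraries.
* The per-class colours of published mask figures are not recoverable;
  the default 6-colour palette is arbitrary but fixed, and indexed PNG
  storage keeps labels authoritative regardless of palette.
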