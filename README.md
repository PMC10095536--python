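# leukoseg

Semantic segmentation of leukocytes (white blood cells) in stained
blood-smear microscopy images. Differential counts of the five leukocyte
types — neutrophils, eosinophils, basophils, monocytes and lymphocytes —
are a routine diagnostic signal, but smear photographs vary widely in
illumination and background colour, and the cytoplasm of a leukocyte is
easily confused with surrounding red blood cells. `leukoseg` implements a
full pipeline addressing this:

* **AHE-Retinex enhancement** — contrast-limited adaptive histogram
  equalization on the HSV value channel, followed by multiscale retinex
  with color restoration (MSRCR) on the RGB channels. Single-scale
  retinex estimates the log-reflectance `R = log I − log(F_σ ∗ I)` with a
  Gaussian surround `F_σ`; MSR averages three scales; the colour gain
  `c_i = α·log(β·S_i / Σ_j S_j)` (α = 46, β = 125) corrects the colour
  shift before a percentile stretch back to 8-bit.
* **CBAM U-net** — a U-net with a VGG16-style contracting path whose four
  skip connections each pass through a convolutional block attention
  module: a channel gate `M_c = σ(MLP(avgpool F) + MLP(maxpool F))`
  followed by a spatial gate `M_s = σ(conv[avgpool_c; maxpool_c])`, both
  multiplying the feature map element-wise. The network and its training
  run on a compact numpy autodiff core shipped in `leukoseg.nn`.
* **Focal + Dice loss** — `L = L_dice + L_focal` with
  `L_focal = −(1−p_t)^γ log p_t` (γ = 2) and soft per-class Dice
  `2TP/(FP+2TP+FN)`, countering the extreme background/foreground
  imbalance of smear images.
* **Metric suite** — precision, recall, F1, per-class IoU, pixel accuracy
  and mIoU, all derived from the K×K confusion matrix.
* **Two-phase training** — 9:1 train/test split, Adam, encoder frozen
  first, then the whole network fine-tuned.
* **Synthetic smear generator** — deterministic scenes with uneven
  backgrounds, red-cell distractors and five leukocyte phenotypes
  (lobed, bilobed-granular, granule-obscured, kidney-shaped, round
  nuclei) plus pixel-perfect masks, so every stage is testable without
  any dataset download; single-cell tiles can be stitched into
  2×2 / 3×3 / 4×4 composites on a 512×512 canvas.

## Worked example

Train a width-reduced CBAM U-net on the colour-separable synthetic task
(40 images of 64×64, 4 classes, 32 train / 8 held out) with the
freeze-then-unfreeze schedule:

```python
from leukoseg import synthdata, pipeline, metrics
from leukoseg.attention_unet import ModelConfig
from leukoseg.losses import LossConfig

pairs = synthdata.make_easy_task(40, size=64, seed=103)
train_set, val_set = pairs[:32], pairs[32:]
mcfg = ModelConfig(num_classes=4, input_size=(64, 64), base_width=8)
tcfg = pipeline.TrainConfig(batch_size=1, learning_rate=3e-3,
                            frozen_epochs=2, unfrozen_epochs=2,
                            seed=3, input_size=(64, 64))
net, hist = pipeline.train(tcfg, mcfg, LossConfig(), train_set, val_pairs=val_set)
for e in hist.epochs:
    print(f"{e['phase']:>9}  loss={e['train_loss']:.3f}  val mIoU={e['val_miou']:.3f}")
print(metrics.report(pipeline.evaluate(net, val_set, 4)["confusion_matrix"]).table())
```

prints

```
   frozen  loss=1.396  val mIoU=0.229
   frozen  loss=0.902  val mIoU=0.374
 unfrozen  loss=0.967  val mIoU=0.632
 unfrozen  loss=0.631  val mIoU=0.878
       class       P%       R%      F1%     IoU%
     class_0    97.33    99.15    98.23    96.52
     class_1    99.53    90.29    94.68    89.90
     class_2    98.42    98.77    98.59    97.22
     class_3    86.35    75.70    80.67    67.61
accuracy: 97.04%   mIoU: 87.81%
```

The loss falls across both phases and the held-out mIoU climbs from the
untrained ~0.2 (all-background prediction) to 0.88: the encoder-frozen
phase already learns the decoder and attention gates, and unfreezing
lifts the remaining classes. Class 3 is the hardest because its blobs
are the rarest in this draw.

A command-line interface wraps the same functionality:

```sh
leukoseg synth --n 50 --grid 2 --seed 7 --out data/synth
leukoseg enhance --in data/synth/images --out data/enhanced
leukoseg train --config run.yaml
leukoseg segment --weights runs/run/last.npz --in img.png --out mask.png
leukoseg evaluate --pred preds/ --truth data/synth/masks --classes 6
```

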