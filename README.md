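# cd31quant

Quantification of the tumour vasculature micro-environment from CD-31
immunohistochemistry (IHC) images of breast tissue.

CD-31 (PECAM-1) stains the endothelium brown (DAB) over a blue
hematoxylin counterstain, so blood vessels appear as annular — often
fragmented — walls around unstained lumina. Manual microvessel counting
on such slides is slow and subjective. This package implements an
automated pipeline for pathologists and image-analysis researchers:

1. **Segmentation** — a U-Net (reflection padding, batch norm, leaky
   ReLU, softmax head) classifies every pixel into ten tissue classes
   (vessel, CD-31⁺ leukocyte, nerve, smooth muscle, lymphocyte cluster,
   tumour, benign epithelium, adipose, stroma, background). Training
   minimises a class-weighted soft Dice loss

   L(p,g) = 1 − Σ_j (w_j/Σ_l w_l) · 2Σ_i p_ij g_ij / (Σ_i p_ij + Σ_i g_ij),

   with vessels weighted 10, rare classes 5, intermediate 2, prevalent 1.
   The network and optimiser are implemented in pure numpy and run on a
   CPU, fully seeded.
2. **Inference** — 512 px sliding window with 128 px overlap, blending by
   a linear center-distance ramp, then per-pixel majority voting.
3. **Post-processing** — Gaussian smoothing of all probability planes
   except vessels/leukocytes, then four ordered hole-filling rules
   (background <10000 px, stroma <1000 px, adipose <10000 px with
   vessel/leukocyte protection, and unlimited vessel hole filling, which
   recovers filled vessels from annular staining).
4. **Morphometry** — per-vessel area (µm²), circularity 4πA/P², axis
   ratio of the minimum-area rotated bounding rectangle, sphere-fitting
   thickness from the distance map and skeleton, and density per mm² of
   stroma; vessels under 40 px (≈10 µm²) are discarded as noise.
5. **Regional analyses** — tumour/adipose/stroma partition by 150 µm
   alternating dilation, 25 µm distance rings around vessels or tumour,
   lymphocyte percentage, tumour–stroma ratio, TIL percentage, and
   t-tests with Benjamini–Hochberg correction.
6. **Validation** — Dice/Jaccard, a 10×10 confusion matrix, and
   instance-level detection under the >50%-overlap rule with split/merge
   accounting.

A seeded synthetic-scene generator (annular, optionally fragmented vessel
walls; nuclei; adipose vacuoles; lymphocyte clusters; stroma texture)
provides exact ground truth so the entire pipeline is testable with no
patient data.

## Worked example

Train a small network on synthetic tiles, run the pipeline on a held-out
scene, and quantify the vessels:

```python
import numpy as np
from dataclasses import replace
from cd31quant import (SynthConfig, generate_scene, NetConfig, TrainConfig,
                       ClassWeights, build_unet, train, predict_slide,
                       postprocess, PostprocessConfig, label_vessels,
                       vessel_table, TissueClass)
from cd31quant.validation import dice_jaccard

cfg = SynthConfig(canvas_px=96, n_vessels=3, n_tumour_nests=0, n_adipose=1,
                  n_lymphocyte_clusters=1, n_leukocytes=1,
                  vessel_outer_radius_px=(5, 9), vessel_wall_px=(2, 3.5),
                  vessel_elongation=(1, 2), adipose_radius_px=(5, 8),
                  lymph_radius_px=(5, 8), leukocyte_radius_px=(1.5, 2.5))
tiles = [generate_scene(replace(cfg, seed=100 + i)) for i in range(64)]
net = build_unet(NetConfig(depth=2, base_channels=8, tile_px=96), seed=0)
train([(rgb, lm.one_hot()) for rgb, lm, _ in tiles], net,
      TrainConfig(epochs=12, batch_size=8, lr=1e-2, seed=0), ClassWeights())

rgb, truth, _ = generate_scene(replace(cfg, seed=900))
# hole thresholds scaled to the 96 px toy canvas
post = PostprocessConfig(smoothing_sigma=1.0, background_hole_px=100,
                         stroma_hole_px=100, adipose_hole_px=100)
pred = postprocess(predict_slide(rgb, net, tile_px=96, overlap_px=32, meta=truth.meta), post)
dice, _ = dice_jaccard(pred.mask(TissueClass.VESSEL), truth.mask(TissueClass.VESSEL))
print(f"vessel Dice: {dice:.3f}")
for row in vessel_table(label_vessels(pred), truth.meta):
    print(f"area {row['area_um2']:6.1f} um^2  circ {row['circularity']:.2f}  "
          f"axis {row['axis_ratio']:.2f}  thick {row['thickness_um']:.2f} um")
```

Typical output (seeds as above):

```
vessel Dice: 0.959
area   33.7 um^2  circ 1.00  axis 1.08  thick 2.62 um
area   28.6 um^2  circ 1.00  axis 1.60  thick 2.38 um
area   21.3 um^2  circ 1.00  axis 1.44  thick 2.00 um
```

Each line is one detected vessel: its surface area, how circular it is
(1 = perfect circle), its elongation (long/short edge of the fitted
rectangle) and its mean wall-fitting sphere radius. The Dice score
compares the predicted vessel mask — including lumina recovered by hole
filling — against the filled ground truth.

A command-line interface mirrors the library:
`cd31 synth`, `cd31 rasterize`, `cd31 tile`, `cd31 train`, `cd31 infer`,
`cd31 quantify`, `cd31 regions`, `cd31 validate` (see `cd31 --help`).

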