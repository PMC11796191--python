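# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `cd31quant`, and what the synthetic-data experiments do and
do not demonstrate.

## Problem setting

CD-31 (PECAM-1) immunohistochemistry highlights endothelial cells with a
brown DAB chromogen on a blue hematoxylin nuclear counterstain. Because only
the endothelium stains, vessels appear as annuli with unstained lumina, and
often as fragmented arcs where the stain binds unevenly or the wall leaves
the section plane. The package segments ten tissue classes — vessel,
CD-31-positive leukocyte, nerve, vascular smooth muscle, lymphocyte
cluster, tumour, benign epithelium, adipose, stroma and slide background —
and quantifies the vasculature within micro-environment regions. Images are
assumed to have a single isotropic pixel size; the default, 0.5034 µm, is
the package-wide assumption for 20x scans and can be overridden everywhere
it matters.

Class codes are ordered by overwrite precedence (vessel = 0 strongest,
background = 9 weakest). The same order resolves rasterization overlaps and
argmax ties during voting.

## Segmentation model

A standard U-Net operates on 512×512 RGB tiles (any size divisible by
`2^(depth-1)` works). Every convolution is preceded by reflection padding
so feature maps never shrink; batch normalisation follows each convolution
and leaky ReLU (slope 0.01) is the activation, avoiding dead units; the
decoder upsamples nearest-neighbour followed by a convolution; the final
layer is a per-pixel softmax. Defaults: depth 5, 32 base channels doubling
per level (capped at 256). None of these sizes is critical to the method;
the test suite exercises a depth-2, 8-channel variant on 96 px tiles.

The network, its backpropagation and the Adam optimiser are implemented
directly in numpy (im2col convolutions, exact adjoints verified against
finite differences in the tests). This keeps the whole pipeline

* runnable on a single CPU with no accelerator stack, and
* bit-reproducible under a seed.

It is a compact implementation of the standard architecture, not a new
architecture.

### Training objective

The loss is a class-weighted soft Dice complement:

    L(p, g) = 1 − Σ_j (w_j / Σ_l w_l) · (2 Σ_i p_ij g_ij + s) / (Σ_i p_ij + Σ_i g_ij + s)

with weights chosen by prevalence and importance: adipose/stroma/background
1, tumour/benign/lymphocyte/muscle 2, leukocyte/nerve 5, vessel 10
(sum 31). Smoothing `s` handles classes absent from both prediction and
truth. Two regimes are deliberate:

* **Evaluation (`s = 0`)**: an absent class contributes Dice 1 by
  convention, so the loss is exactly 0 at perfect one-hot agreement, 1 at
  total hard disagreement, and matches hand-computed values (e.g. the
  single-class two-pixel case g=[1,0], p=[1,1] gives 1/3).
* **Training (`s = 1`, the `TrainConfig` default)**: keeps gradients
  finite near empty classes; an unconditional smoothing term is not used
  for evaluation because it would distort the exact anchor values above.

An optional ignore mask excludes unannotated pixels from every sum —
the minimal faithful mechanism for training on partially annotated slides.

Optimisation: Adam with an exponentially decaying learning rate
(0.97/epoch) modulated by cosine warm restarts (period 25 epochs, floor
10% of the envelope). Initial rate 1e-3 for the full-size network; the
scaled-down smoke runs use 1e-2, where the tiny network occasionally
plateaus at lower rates (Adam step sizes are scale-normalised, so escape
time from a flat region is inversely proportional to the rate). Batch
size 8 by default; batch size is hardware-bound, not part of the method. Augmentation: random flips, quarter turns (exact pixel
permutations), free-angle rotation with mirror padding (nearest-neighbour
for labels, so masks stay one-hot), and brightness/contrast/saturation
±10% with hue ±0.02.

## Inference

Whole images are predicted in 512 px tiles with 128 px overlap (stride
384); the last window along each axis is shifted to end at the border.
Tile probabilities are blended with weights

    w(x) = max(1 − d_∞(x)/d_max, 1e-3),

a linear ramp in the Chebyshev distance to the tile center, floored so
border pixels covered by a single tile retain their mass, then
renormalised per pixel. Majority voting is per-pixel argmax of the blended
mean; exact ties go to the lower class code (the higher-precedence
tissue). Images smaller than a tile are mirror-padded and cropped back.

## Post-processing cascade

Gaussian smoothing (sigma 2 px by default) is applied to every probability
plane except vessels and leukocytes, whose fine detail must survive; then
four hole-filling rules run in order:

1. background holes < 10000 px → background (no protection);
2. stroma holes < 1000 px → stroma, never overwriting vessel/leukocyte;
3. adipose holes < 10000 px → adipose, same protection;
4. vessel holes → vessel, overwriting anything, no size limit.

A hole is a 4-connected component of non-class pixels fully enclosed by
the (8-connected) class — the standard connectivity duality. Thresholds
compare strictly ("smaller than"). Rule 4 is what turns annular
vessel-wall predictions into the filled vessels that all morphometry
assumes. Note the asymmetry: rule 1 carries no protection, so a vessel
fragment marooned inside a small background hole can legitimately be
removed; the protection guarantee is that vessel/leukocyte pixels are
never consumed by the stroma/adipose rules. Rule 4 may also absorb
leukocyte pixels enclosed by a vessel. The cascade is empirically
idempotent on fuzzed label maps (verified over seeded random maps in the
tests); we know of no counterexample, though idempotence is not proven.

## Vessel morphometry

Vessels are 8-connected components of the vessel class; components under
40 px (≈10 µm² at 0.5034 µm pixels) are noise and discarded. Per instance:

* **Area** — pixel count × pixel area (µm²).
* **Circularity** — 4πA/P², clipped at 1. The perimeter is a sub-pixel
  marching-squares contour length on a lightly smoothed mask (sigma
  scaled to the inscribed radius, capped at 2 px). Naive pixel-edge
  counting would give a disk ≈0.78 and staircase contours ≈0.89; with
  smoothing a digital disk of radius 50 px measures 1.000. Shapes within
  a few pixels of the size floor overshoot slightly before clipping.
* **Axis ratio** — long/short edge of the minimum-area rotated rectangle
  over the pixel corners (convex hull + rotating calipers; corners rather
  than centers so an n×m block measures exactly n×m). For weakly
  elongated objects under ~20 px across, the one-pixel rasterization
  footprint biases the fitted rectangle toward squares; the recovery
  tests therefore use clearly elongated vessels ≥ ~40 px across, where
  agreement with the drawn elongation is within 5%.
* **Thickness** — Euclidean distance map + skeleton sphere fitting: at
  every skeleton pixel a disk of radius equal to the distance value is
  stamped carrying that value, keeping per-pixel maxima; thickness is the
  mean stamped value over the instance, in µm. The skeleton is the medial
  axis augmented with distance-ridge local maxima, because discrete
  medial axes can miss the deepest pixel of round components and truncate
  the largest sphere. Against a brute-force maximal-inscribed-disk oracle
  the mean relative error over random blobs is ~2% (tested bound 5%).
  The reported value is the fitted *radius*, following the stated
  construction; `thickness_scale="diameter"` doubles it for the
  trabecular-thickness convention in the literature this measure derives
  from.
* **Density** — vessels per mm² of stroma (stroma ∪ lymphocyte pixels)
  within a region. A vessel belongs to the region containing its
  centroid snapped to the nearest instance pixel, so a straddling vessel
  counts exactly once. Zero stromal area reports missing (NaN), never 0.

## Regional analyses

* **Partition**: tumour and adipose components ≥ 1000 px are dilated
  150 µm in alternating 5 µm increments, each increment clipped to tissue
  and forbidden from claiming the other's pixels; the remainder of the
  tissue (lymphocyte clusters included) is the stroma region. Dilations
  use cumulative Euclidean-distance thresholds from the original masks —
  equivalent to repeated disk dilation but isotropic and free of
  per-step discretisation loss. The 5 µm turn length makes the meeting
  front near-equidistant when the two regions collide.
* **Rings**: ring k around a seed holds pixels at Euclidean distance
  ((k−1)·25, k·25] µm, clipped to tissue and excluding the seed. Defaults:
  8 rings around vessels, 12 around tumour. Lymphocyte percentage per
  mask is 100·|lymphocyte|/|stroma ∪ lymphocyte|.
* **Composition**: tumour–stroma ratio = tumour / (stroma ∪ lymphocyte)
  area inside the tumour region; TIL percentage is the lymphocyte
  percentage there. Empty denominators report missing.
* **Statistics**: two-tailed t-tests (paired for consecutive rings, two-
  sample otherwise) with Benjamini–Hochberg adjustment (scipy); Pearson
  correlation per vascular parameter for predicted-vs-truth comparisons.

## Detection metrics

A predicted vessel covering > 50% of a true vessel's pixels is a true-
positive candidate; predictions are matched one-to-one greedily by
descending coverage (ties by truth size, then index). Since disjoint
predictions' coverages of one truth sum to ≤ 1, at most one prediction can
clear 50% of any truth, so greedy matching attains the maximum matching —
verified against an exhaustive matcher on random scenes. Merges are truths
(≥2 per prediction) covered >50% by the same prediction; splits are truths
covered >10% by ≥2 predictions with none above 50% (both thresholds
configurable; the 10% floor keeps incidental slivers from counting).
Multi-image metrics pool counts (micro-average).

## Synthetic scenes

The generator emulates, at the level the pipeline is sensitive to:
DAB-brown elliptical vessel walls with unstained lumina and optional
angular wall gaps (RGB only — ground truth stays the filled vessel),
nuclei-stippled tumour nests, dense lymphocyte clusters, white adipose
vacuoles, pale nerves, small brown leukocytes, textured pink stroma and
near-white background, plus blur and sensor noise. Structures are placed
by rejection sampling without overlap; impossible requests raise rather
than truncate. Everything is a pure function of the seed.

It does **not** model: extravascular red blood cells (a real confounder
noted as a limitation of the stain), staining gradients, scanner
artefacts, tissue folds, or realistic nuclear morphology. Passing the
synthetic smoke test therefore demonstrates that the pipeline mechanics
(learning, stitching, hole filling, measurement) are correct — not that
the default network would reach the same accuracy on patient slides.

A separate calibration generator scatters lymphocyte dots uniformly
around a central tumour disk (dots may touch the seed, so no exclusion
bias exists near the boundary). Ring profiles over such scenes must be
statistically flat; the tests require paired-t/BH non-significance in
≥ 90% of seeded replicates, calibrating the ring analysis itself.

## Scaled-down test conditions

CPU test runs use 96 px scenes with three small vessels (radius 5–9 px,
walls 2–3.5 px, 25% fragmented), a depth-2/8-channel network, 64 training
tiles and 12 epochs at rate 1e-2; held-out vessel Dice after the standard
pipeline reached ≈0.9–0.97 across pilot seeds against an acceptance floor
of 0.8. The hole-filling thresholds scale with the scene (100 px on the
96 px canvas): the slide-scale defaults are absolute pixel counts that
exceed the entire toy canvas, under which the unprotected background rule
would swallow whole vessels whenever the model labels an unstained lumen
as background. The ring calibration uses 20 replicates of 6 images
(512 px, 1 µm pixels, 6 rings of 25 µm). These sizes are the package's
chosen study conditions for desk-scale verification.

## Known limitations

* Cross-validation scores on patient data are out of scope; no trained
  weights ship with the package.
* Lymphatic and blood vessels are not distinguished (CD-31 stains both).
* The minimum-area-rectangle axis ratio is biased toward 1 for small,
  weakly elongated vessels (rasterization footprint).
* Whole-slide density uses stroma (incl. lymphocytes) as the denominator
  everywhere, including outside the tumour analysis, by the density
  definition; total-tissue density is not reported.
* Single-resolution images only; pyramids are read at level 0.
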