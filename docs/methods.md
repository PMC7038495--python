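# Methods

This note records the models the package implements, the numeric
conventions it commits to, the parameters that matter, and what the
synthetic benchmark does and does not establish.

## Background model and segmentation

Each calendar day's frames are averaged pixelwise into a background
`B_d`; with hourly acquisition that is 24 frames. The model assumes a
fixed camera and a mostly static scene, so each transient object pollutes
the mean at only 1/n strength. The consequence is worth stating: with few
frames per day (e.g. 4), object "ghosts" reach a quarter of the object's
own contrast and the subtraction stage degrades sharply. The pipeline is
designed for n ≈ 24.

Segmentation computes the **absolute** grayscale difference between the
enhanced frame and the background. Absolute rather than signed: darker-
than-background elements (cast shadows are their own target class) must
segment as well as brighter ones.

Both sides of the subtraction are enhanced identically (config
`segment.enhance_background`, default on). CLAHE remaps intensities
globally per image; enhancing only the observation frame leaves a
systematic frame-vs-background offset across the entire image (median
residual ≈ 18 gray levels on synthetic fixtures vs ≈ 1 when both sides
are enhanced), which buries real objects in threshold noise. The
alternative ordering remains available for experimentation.

Defaults (all in `PipelineConfig`): CLAHE clip 2.0, 8×8 tile grid;
bilateral diameter 9 px, σ_color 75 intensity levels, σ_space 75 px;
binary threshold 40 (chosen once by scanning {25, 35, 40, 45} on seeded
synthetic fixtures: 40 yields recall ≥ 0.97 at ≈ 0.1 false positives per
frame); morphology closing(3×3) → opening(3×3) → dilation(3×3); minimum
component area 50 px; 8-connectivity. Working frame size follows the
source cameras' published reduction (3456×5184 → 964×1296); the exact
quarter (864×1296) is one config line away, and `resize` accepts any
explicit target. Boxes are 0-based, top-left origin, half-open.

## Enhancement operators

CLAHE is implemented directly: per-tile 256-bin histograms clipped at
`clip × area / 256` counts with uniform redistribution of the excess, the
textbook CDF mapping `v → round((cdf(v) − cdf_min)/(area − cdf_min) ×
255)`, and bilinear interpolation between tile mappings. A homogeneous
tile (single occupied bin) maps to itself. With one tile and an unbounded
clip the operator reduces exactly to global histogram equalization, which
is how it is oracle-tested. Color frames are equalized on the Y channel
of a full-range BT.601 YCbCr transform.

The bilateral filter is the direct double-Gaussian weighted mean over a
square window (spatial term on pixel distance, range term on intensity
difference), edge-replicated at borders, applied per channel. Both
operators were written against hand-computable definitions rather than
delegating to a library precisely so their semantics are pinned by the
tests.

## Global features

The fixed-length vector is `[Hu(7) | Haralick(13) | histogram(512)]`.

**Hu moments** are computed from *area-integral* moments — the
piecewise-constant intensity surface integrated over each pixel's unit
square — rather than point sums at pixel centres. Point-sum moments carry
a per-pixel variance term that breaks scale invariance by ~1% at typical
crop sizes; integral moments make invariance under translation, 90°/180°
rotation, mirroring (sign flip of the seventh invariant) and integer
nearest-neighbour rescaling exact to floating point. Degenerate crops
(all zero, or support on a single pixel) return zeros with a warning: a
point mass carries no shape. Hu values enter the vector raw; the
feature-scaling stage standardizes them where a family needs it.

**Haralick statistics**: gray levels quantized uniformly to 32 bins,
co-occurrence at distance 1, symmetric and normalized GLCMs, the 13
classical statistics (the unstable 14th omitted) averaged over the four
standard directions. Conventions: logarithms base 2; sum variance centred
on the sum average; correlation defined as 0 for a constant crop. GLCM
construction uses `skimage.feature.graycomatrix`; the statistics are
computed here and oracle-tested against hand-enumerated co-occurrence
pairs.

**Color histogram**: joint 8×8×8 RGB histogram over [0, 256)³, flattened
R-major, normalized to sum 1 (B = 512 keeps L = 532 tractable for every
classifier family). Crops are whole-box from the enhanced frame — pixels
outside the contour are kept (context helps, and masking is a config
switch).

## Dataset rules

The 13-class schema is ordered and fixed; confusion matrices and score
columns always use it. The reference collection the defaults emulate has
1934 annotated elements with per-class counts from 96 to 205.

The split is stratified: `floor(0.8 n_c)` per class, topped up by largest
remainder to exactly `floor(0.8 n_total)` = 1547. Balanced augmentation
grows class `c` to `min(37 n_c, 3034)` by label-preserving transforms
(horizontal flip, rotation within ±25°, brightness 0.7–1.3, zoom 0.8–1.2,
each included with probability ½, flip forced if none), copies assigned
round-robin so no original contributes more than 36. Applied to the
reference counts this yields ten classes at the cap, three below (squid
2849, anemone 2886, shadow 2997), total 39 072. Originals are never
dropped; test elements are never touched.

## Classifier registry

Sixteen immutable named configurations (see `classifiers.registry`).
Interpretations the package commits to:

* "number of nodes" for trees/forests is the maximum leaf-node count
  (`max_leaf_nodes`), the most common capacity control matching the
  phrase; "features" is the candidate-feature count per split.
* K-NN neighbour counts are fixed registry entries (39 and 99); k = 39 is
  what the square-root rule yields at n_train = 1547. When a desk-scale
  fixture has fewer than k training elements, k is clamped to n_train
  with a warning.
* The neural networks consume the 1-D feature arrays, so the CNNs
  convolve along the feature axis: blocks of Conv1D(kernel 3) → ReLU →
  MaxPool(2) with filters (32, 64) or (32, 64, 128), then a 13-unit
  softmax head. The dense nets use widths (256, 128, 64) with ReLU then
  tanh activations plus dropout 0.5 (structure 1) or (256, 128, 64, 64)
  all-ReLU (structure 2). Training: CNN1/2 Adadelta, 50 epochs, batch
  356; CNN3/4 RMSProp, 150 epochs, batch 128; DNN1/2 RMSProp, batch 518;
  DNN3/4 SGD, batch 356; 500 epochs for all DNNs. Optimizer internals are
  pinned: SGD lr 0.01; RMSProp lr 0.001, ρ 0.9; Adadelta lr 1.0, ρ 0.95.
  The networks are a compact numpy implementation (im2col convolutions,
  inverted dropout, Glorot init, float32) with one seeded generator
  driving init, shuffling and dropout, so training is bit-reproducible.
* Scale-sensitive families (SVM, K-NN, CNN, DNN) see z-scored features;
  the scaler is fitted on the training split only. Trees and forests
  consume raw features.
* Margin models (LinearSVC, SGD hinge) have no native probabilities;
  their score rows are a softmax over decision values — monotone in the
  margins, hence valid for ROC construction. Probabilistic families
  return true probabilities (vote fractions for K-NN and forests).
  Score rows span the full 13-class order; the predicted label is the
  argmax with ties broken by class order. Single-class training data is
  fatal for margin/NN models (a constant predictor would be meaningless);
  K-NN and trees handle it naturally.

## Evaluation

Accuracy is the plain multiclass diagonal fraction (the binary
(TP+TN)/(TP+FP+TN+FN) is its two-class case); per-class recalls are
reported alongside since "macro accuracy" is ambiguous. AUC is the
unweighted mean of one-vs-rest ROC AUCs over classes present in the
truth (absent classes excluded with a warning), trapezoidal integration
with ties grouped — equal to the concordant-pair probability with half
credit for ties, which is how it is property-tested. Loss is categorical
cross-entropy of the true-class score, clipped at 1e-12 so vote-frequency
scores stay finite.

Cross-validation stratifies over **original** elements; augmentation is
re-run inside each training fold. Folding an augmented set would place
near-duplicate siblings of validation elements in the training fold and
inflate every metric; the package refuses that design. Per-fold seeds are
derived from the base seed, and the report retains per-fold metrics, the
pooled confusion matrix, and the validation-fold partition.

Time series count classified detections per calendar day; days without
detections report 0. Because "images with at least one detection" and
"total detections" answer different questions, both are carried and both
appear in the automatic-vs-manual comparison.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes: a
static background (base color plus smoothed Gaussian mottling), hourly
frames, per-class object appearances (ellipses, star polygons, crosses;
stripe/speckle textures; colors chosen so every class keeps ≥ ~25–30 gray
levels of luminance contrast against the background under its texture
extremes), additive soft-edged turbidity clouds, multiplicative soft
shadows, and i.i.d. Gaussian sensor noise added last. Planting counts per
class per frame are deterministic integers (or per-day sequences), so
truth counts are seed-independent; all sampling comes from one generator
seeded by `spec.seed` in a documented order, making sequences
bit-reproducible. Objects are placed with disjoint bounding boxes (4 px
margin) and never partially off-frame.

What it does *not* emulate: camera motion, illumination drift within a
day, occlusion and overlap between animals, photorealistic water optics,
class-imbalanced arrivals, or appearance variation within a class beyond
texture noise. Passing the end-to-end suite therefore establishes that
the machinery is correct and that the feature stack separates genuinely
distinct appearances — not that real-footage accuracy will match the
synthetic numbers.

## Problem sizes and numerical choices

The default test suite runs the end-to-end check on one hourly day of
320×320 frames (24 frames, 312 planted objects, ≥ 20 per class) and
benchmarks the classifier registry on a 260-element feature table —
sizes chosen so the full suite completes in minutes on one core while
every class still has ≥ 10 elements for 10-fold CV. Detection quality is
scored at IoU ≥ 0.3 against truth boxes; a detection overlapping no truth
box at IoU ≥ 0.05 counts as a false positive. Ties in all argmax
decisions resolve to the lower index (schema order). uint8 rounding is
half-to-even throughout (numpy convention).

## Known limitations

* The daily-mean background degrades with sparse days (ghosting) and
  would need robust averaging (median, trimmed mean) for gappy archives.
* Overlapping animals merge into one detection; no tracking or instance
  splitting is attempted.
* The numpy networks are adequate for 532-long inputs at desk scale but
  are not a general DL substrate (no GPU, no batch norm, no schedules).
* `LSVM` probabilities are rank-faithful but uncalibrated; AUC is
  unaffected, loss values for margin models should be compared only
  within a family.
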