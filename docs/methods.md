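# Methods

This note records the modeling assumptions, numerical conventions and
design choices behind `nucmil`, at the level of detail a maintainer or
reviewer needs to interpret its outputs.

## Problem setting

Whole-slide classification is weakly supervised: a slide (bag) has a
binary label, its tiles (instances) do not, and a slide is positive iff
at least one instance is positive. The model combines three analysis
scales: slide-level attention-pooled deep features make the decision;
patch-level and nuclei-level losses act as penalty terms that
regularize it. Nucleus segmentations are *inputs* — in production they
would come from an external instance segmenter; here the synthetic
generator provides ground-truth masks, and a toy threshold segmenter
exists for synthetic fixtures only.

## Nucleus morphometry

**Coordinates** are 0-based with x = column, y = row. Raw moments
`M_pq = Σ x^p y^q H(x,y)` and central moments are computed over the
binary mask; the area-normalized second central moments
(μ̄₂₀, μ̄₀₂, μ̄₁₁) define the equivalent ellipse.

**Axis lengths.** `Major/Minor = sqrt(8(μ̄₂₀+μ̄₀₂ ± sqrt(4μ̄₁₁² +
(μ̄₂₀−μ̄₀₂)²)))` — the standard image-ellipse axes. A transcription of
these formulas without the outer square root would carry px² units and
be dimensionally inconsistent with ellipticity and equivalent diameter,
so the rooted form is used. Orientation is `θ = ½·arctan(2μ̄₁₁ /
(μ̄₂₀−μ̄₀₂))`, confined to (−π/4, π/4] by the arctan branch; when the
denominator vanishes, θ is 0 or ±π/4 by the sign of μ̄₁₁. Note the
branch gives θ a period of π/2: a quarter-turn of the mask leaves the
reported θ numerically unchanged (the directional boundary counts swap
instead). Degenerate (collinear/singleton) masks clamp Minor to 1 px
and flag the region.

**Perimeter.** The contour is the set of foreground pixels with at
least one background 4-neighbor. N_v/N_h/N_d1/N_d2 count unordered
pairs of contour pixels adjacent along 90°/0°/45°/135°; the perimeter
is `N_v + N_h + w(N_d1 + N_d2)` with diagonal weight w = 2 by default
and √2 as a config switch (`diagonal_weight`). The printed-2 convention
is kept as default because it is what the feature definitions state;
the √2 variant is the geometrically faithful alternative.

**Convex hull.** Hull of foreground *pixel centers* (Qhull), area by
the shoelace formula on the hull polygon, perimeter as polygon length.
Center-based hulls undershoot the pixel-count area of convex shapes by
up to ~3% (digitization); tests assert hull-vs-region consistency up to
that slack. Collinear masks fall back to hull area = region area,
flagged.

**Texture.** The gray patch is linearly quantized to l = 8 levels
(l is a free parameter; 8 stabilizes co-occurrence statistics on
nuclei of a few hundred pixels). GLCMs are accumulated over the four
offsets (1,0), (1,1), (0,1), (−1,1), counting only pairs with both
pixels inside the nucleus mask, normalized per direction; contrast,
dissimilarity, homogeneity, entropy (log₂, 0·log0 := 0), angular
second moment and dispersion (squared deviation from the uniform cell
mass 1/l²) are averaged over the four directions (per-direction
concatenation would quadruple the width; averaging is the common
convention). Roughness = nucleus perimeter / hull perimeter, with the
nucleus perimeter taken to be the directional-count perimeter above
(only one nucleus perimeter is defined). A nucleus too small to form a
pair in every direction raises a degenerate-GLCM error and is skipped
by the batch featurizer.

The 16-vector order is fixed: [Major, Minor, Area, θ, Ecc, Ell, Dia,
Per, AreaHull, Con, Diss, Hom, Ent, ASM, Rou, Dsip].

## Nucleus graphs and message passing

Edges join nuclei that are among each other's K = 5 nearest neighbors
(ties at the K-th distance broken by lower node index) *and* closer
than d_min = 50 px, symmetrized by union (intersection available).
One graph spans one selected patch; the graph inherits the slide
label. Node order is canonicalized (lexicographic by centroid) inside
`build_knn_graph`, which makes every downstream computation — including
trained-network logits — bit-exactly invariant to input permutation,
not merely invariant up to float reordering.

Message passing follows the multi-aggregator degree-scaling recipe:
per-edge messages M([h_src, h_dst]) are reduced per node by mean, std,
max and min, each modulated by scalers `(log(d+1)/δ)^α` for
α ∈ {0, +1, −1}; δ is the mean of log(degree+1) over training-split
nodes, computed once and frozen. Isolated nodes aggregate to zeros (the
statistics are undefined on empty neighbor sets). Two layers, hidden
width 64, message width 32, ReLU between layers; graph logits from
global mean pooling and a linear head; an empty graph falls back to a
learned null embedding, flagged. Depth and widths are unstated in the
source setting; these are desk-scale defaults, all configurable.

## Attention MIL

The exact composition of the gated attention score is genuinely open;
the implemented reading is: a shared linear trunk (1024 → 256, ReLU)
projects patch features; each branch applies multi-head self-attention
(4 heads, d_K = 64) over the trunk bag followed by a linear map to a
64-d gate space; the sigmoid branch gates the tanh branch elementwise;
a final 1-d projection and a bag softmax produce the scores. A
`gated_plain` variant (linear branch transforms, no self-attention) is
available for ablation. The slide feature is the score-weighted sum of
the **raw** 1024-d patch features — a convex combination, so each
coordinate stays within the bag's per-dimension range.

Two choices matter for robustness and were fixed after observing
training behavior on held-out generator seeds:

* the final score projection is **zero-initialized**, so attention
  starts as exact mean pooling and sharpens only as gradient arrives;
  randomly initialized attention can pool misleading patches early and
  lock the slide head into confident errors;
* the trunk is **shared** between the attention branches and the patch
  head, so the patch-level penalty shapes the representation that
  drives attention. Without any shared parameters the penalty branches
  could not influence slide predictions at all (top-c selection is
  discrete and carries no gradient).

Patch-level supervision uses the top-c instances labeled with the
slide label plus the bottom-c labeled negative
(`use_bottom_instances`, default on).

## Losses and training

APL = NCE + RCE. NCE = CE / Σₖ(−log p(k)) ∈ [0, 1]; RCE clips log 0 at
A = −4, so RCE ≤ −A; predicted probabilities are floored at 1e−7 inside
logs. The active term can be switched to plain CE. The slide loss is
ordinary cross-entropy; the total is the exact weighted sum with
default weights (0.7, 0.2, 0.1). Ablations renormalize the remaining
weights proportionally: slide-only (1, 0, 0), slide+patch
(0.7, 0.2, 0)/0.9, slide+nuclei (0.7, 0, 0.1)/0.8.

Training: stratified 7:1:2 split (per-class rounding; 476 slides give
333/47/96), one Adam step per slide, attention recomputed every epoch,
patch features and nucleus features z-normalized with training-split
statistics, δ fit on training graphs only. Defaults: lr 5e−3, 20
epochs, batch 1, no schedule; early stopping on validation total loss
with patience 10 and best-validation checkpointing. Learning rate,
batch size and epochs are not prescribed by the source setting; 5e−3
is the package default because desk-scale runs (42 training slides, 9
patches each) need to converge within 20 epochs — at 1e−4 the model is
still far from its plateau when the budget ends. Decoupled weight
decay is available (default 0). All randomness derives from the config
seed; two runs with the same seed produce identical loss histories.

## Synthetic data: what it emulates, what it does not

Each slide is a 3×3 grid of 512-px tiles surrounded by one tile of
blank glass; tiles contain 8–16 non-overlapping rotated ellipses
(rejection-sampled centers, 1.5 px guard band) rendered dark on a light
background with additive Gaussian texture noise, tinted to a saturated
hue so saturation-channel tissue extraction is exercised. Per-class
rendering distributions (gamma areas, normal aspect ratios and
intensities) default to the observed cancer/normal contrasts the
handcrafted features target: mean-area ratio 1.3726, rounder shape
(ellipticity ratio ≈ 1.03), darker (intensity 85 vs 100 on a 225
background) and noisier (σ 22 vs 14) chromatin. In a positive slide a
`witness_rate` = 0.7 fraction of tiles (always ≥ 1) carries cancer-like
nuclei — the MIL bag assumption. A `scale` parameter rescales linear
dimensions, since no magnification is canonical for the nucleus
statistics.

Ellipses make analytic truth available (axes, area, orientation), which
is what the parameter-recovery tests exploit. The generator does *not*
emulate H&E color variation, stain artifacts, nucleus clustering or
touching nuclei, subtype morphology, or scanner heterogeneity — passing
tests therefore demonstrate that the pipeline's machinery is correct
and that the method detects the configured morphological contrasts at
realistic noise levels, not that it would reach the same operating
point on clinical cohorts.

The default feature extractor is a deterministic, seeded Gaussian
random projection of per-block gray statistics (12×12 blocks: mean,
spread, dark-pixel fraction) concatenated with global dark-object
morphology statistics (component count, mean/sd component area, dark
intensity, within-object spread, dark fraction; replicated ×16 for
geometric weight). The morphology group is what makes the stub an
honest stand-in for a pretrained CNN, whose pooled features are
strongly nucleus-sensitive: with layout statistics alone, slide bags of
the default dataset are not linearly separable at 42 training slides,
while the underlying morphological signal is several σ wide. Any
extractor implementing the `FeatureExtractor` interface (declared
width, determinism flag) can be substituted, e.g. a real CNN backbone.

## Preprocessing

Tissue masking converts RGB→HSV, Otsu-thresholds the saturation
channel (glass is unsaturated), applies a closing with a disk of
radius 2 (idempotent on the result), and removes components below an
area threshold defaulting to 64 tiles' worth of pixels at the masking
level; the synthetic study masks at pyramid level 2 with a 64-px²
threshold, both configurable. Tiles are 512×512 windows on the level-0
grid that intersect the mask; windows overrunning the slide are
discarded rather than padded, keeping tile geometry exact. Recorded
top-left coordinates reassemble the tiled extent pixel-exactly.
Pyramidal WSI formats are deliberately out of scope: the pipeline
consumes plain images and manifests, so a WSI backend is a thin
adapter.

## Evaluation

TP/TN/FP/FN follow the convention positive = cancerous. AC, SP, SE, PC
are printed as percentages rounded half-up to two decimals (raw
fractions are kept alongside); a zero-denominator ratio is reported as
NA with a warning. The predicted class is the argmax (0.5 threshold);
`PrePro` is the softmax probability of the predicted class. Attention
heatmaps paint min–max-normalized scores at the recorded tile
coordinates at 1/8 scale, optionally alpha-blended over the slide.

## Problem sizes

Defaults throughout are chosen so the full study runs on one CPU:
60 slides × 9 tiles × 512 px, 8–16 nuclei per tile, 20 epochs
(~1–2 min end to end); parameter-recovery statistics use 10,000 nuclei
per class; oracle suites use ≥ 100 random fixtures per operation.

## Known limitations

* The autodiff engine implements exactly the operations the models
  use; it is not a general-purpose framework (no broadcasting matmul,
  no higher-order gradients).
* Nuclei-branch supervision is weak (graph label = slide label), so
  its standalone accuracy is limited by label noise — which is the
  premise for using APL there.
* The toy segmenter merges touching nuclei (flagged, not fixed); real
  use expects an external instance segmenter.
* Handcrafted color features are deliberately excluded (stain
  variability), as are contour Fourier descriptors.
* Multi-class subtyping, ROC/AUC reporting and cross-validation
  orchestration are out of scope.
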