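# Methods

## Staining model and deconvolution

A brightfield IHC image is modelled by the Beer-Lambert law: for detection
channel *c*, transmitted intensity is `I_c = I0_c · 10^(−(A·OD)_c)` with
`I0 = 255`.  Rows of the 3×3 optical-density matrix `OD` are unit stain
absorption vectors — hematoxylin `(0.650, 0.704, 0.286)` and DAB
`(0.268, 0.570, 0.776)` — and, because only two chemical stains are
present, the third row completes the basis as the unit-normalized cross
product of the first two, `(0.636, −0.710, 0.302)`.  Deconvolution inverts
the model per pixel: `A = −log10(I/255) · OD⁻¹` (Ruifrok-style).  Channel 2
of `A` is the DAB absorbance used as the membrane "gray value" everywhere
downstream.

Numerical choices:

* The log is undefined at `I = 0`.  Quantized (integer) detector images are
  floored at intensity 1 (their darkest representable non-zero level);
  continuous float images are floored at `1e-12` only, so the un-quantized
  forward/inverse round trip is exact to machine precision.  Floored-pixel
  counts are reported in metadata.
* Out-of-gamut negative amounts (noise, non-stain pigments) are clipped to
  zero by default — amounts are physical absorbances — and counted.
* The 8-bit round trip degrades as transmitted light darkens: the
  quantizer's absorbance step is `≈ 0.5/(I ln 10)` per channel, amplified by
  at most the maximum column 1-norm of `OD⁻¹`.  For two-stain fields with
  hematoxylin ≤ 0.9 and DAB ≤ 2 this bound is ≈ 0.15 at the darkest
  rendered pixels and ≤ 0.01 while intensities stay above ≈ 40/255.  Tests
  assert the exact identity on the float path and the analytic bound on the
  quantized path.
* Integer rendering rounds half-even (bit-stable fixtures).  Custom stain
  vectors can be supplied as a 3×3 TSV/JSON config; collinear or zero
  vectors raise an invalid-basis error.

## Membrane segmentation

Tiles are converted sRGB → XYZ (D65) → CIE Luv; Luv is perceptually
uniform, so plain Euclidean distance is meaningful for clustering.  k-means
with k = 3, at most 50 Lloyd iterations, and 10 restarts (best inertia
wins) partitions pixels into membrane / nuclei / background groups; the
cluster with the highest mean DAB absorbance is selected as membrane, with
ties broken toward the lowest cluster id for determinism.

Restarts are seeded with k-means++ rather than uniform random pixel
sampling.  On faintly stained tiles the membrane holds only a few percent
of pixels at a modest Lightness offset from background; uniform seeding
then regularly converges, in every restart, to a local optimum that splits
the nuclei and merges membrane into background (observed Dice 0.09 with
15× the k-means++ inertia on the same tile).  k-means++ seeds spread by
squared distance and recover the faint cluster reliably; k, iteration, and
restart counts are unchanged.

Degenerate tiles with fewer than 3 distinct colors are assigned without
clustering (one cluster per distinct color; unused ids flagged empty).  A
`subsample` option fits centroids on ≤ 65,536 sampled pixels and then
assigns all pixels — a speed knob for oversized tiles; the default at
512×512 is a full fit.  Segmentation runs per patch, which keeps memory
bounded and lets patches be processed independently.

## Gray value map

The slide is tiled into 512×512 patches (row-major; edge patches padded
with white and flagged).  Per patch: `A` = mean DAB absorbance over
membrane pixels, `F` = membrane pixels / all patch pixels (the printed
definition — padded white pixels stay in the denominator, slightly
attenuating F at slide edges), `L` = mean Luv Lightness over membrane
pixels.  `L` is carried because heavy DAB staining saturates the blue
channel of the sensor while perceived darkness keeps increasing; Lightness
still tracks the visual gray level there, and the CNN learns to fuse the
two.  `A` is kept in raw absorbance units (no display rescaling); the
training pipeline normalizes per channel later.

A patch is *tissue* when ≥ 2 % of its pixels have `min(R,G,B) < 220`;
non-tissue patches get `(0, 0, 0)` without segmentation, so glass never
contributes signal.  Per-patch k-means seeds derive from
`SeedSequence((slide_seed, row, col))` for reproducibility.  The GrayMax
slide statistic is the maximum `A` over tissue patches — motivated by the
clinical convention that the strongest-staining fraction of the slide
carries the score.

## GrayMax baseline

Two thresholds `t1 < t2` on the slide maximum gray value define the three
reported levels (`v < t1` → 0/1+, `t1 ≤ v < t2` → 2+, `v ≥ t2` → 3+; the
top bin is closed on the left).  Thresholds are fitted per training fold by
exhaustive search over midpoints of consecutive distinct sorted values,
maximizing training accuracy, ties resolving to the smallest pair — the
simplest deterministic ordinal classifier over a scalar statistic.  A
percentile variant of the slide statistic is deliberately out of scope of
the default; the baseline exists to be information-poor.

## Multitask CNN

The GrayMap is normalized (`A` and `L` divided by 99th-percentile constants,
default 2.0 and 100; `F` already a fraction), centered on a zero square
canvas, and classified by a residual CNN: 3×3 conv stem → residual stages
(two 3×3 convs + batch norm each, identity or 1×1-projected skip, stride-2
downsampling between stages) → global average pooling → two dropout +
linear sigmoid heads, a 3-way one-vs-rest head for the IHC level and a
binary head for FISH status.  All activations are learnable per-channel
PReLU (initial slope 0.25) with matched Kaiming initialization — there are
no pretrained weights at these input statistics, and PReLU avoids dead
units.  The loss is the equal-weight sum of the heads' sigmoid
cross-entropies (no softmax; argmax at inference; per-head label masking
supports slides without FISH results).  Training uses Adam (base LR 0.001)
annealed by a cosine schedule to 1e-8, with augmentation: random rotation
±180°, horizontal/vertical flips, random crop at a 0.75 canvas ratio, and
*paste synthesis* — a donor slide of the same FISH status and CV fold but
strictly lower IHC level is translated into the blank canvas space of the
target (20 placement tries, else unchanged), keeping the target's labels.
Inference is deterministic: center crop, no dropout, batch-norm running
statistics.

The reference geometry is a ResNet18-style backbone (base width 64, stages
2-2-2-2, 680×680 canvas, 512 crop).  All experiments in this repository use
the reduced geometry `desk_config()` — canvas 64, crop 48 (same ratio),
base width 8, stages 1-1, batch 8 — which trains in minutes on one CPU;
the model family, loss, schedule, and augmentations are identical.  Layers
and backpropagation are implemented in numpy and verified against central
finite differences (relative error < 1e-4 in tests).

## FISH rules

Groups over the (HER2/CEP17 ratio, mean HER2 copies/cell) plane: G1
(ratio ≥ 2, copies ≥ 4), G2 (ratio ≥ 2, copies < 4), G3 (ratio < 2,
copies ≥ 6), G4 (ratio < 2, 4 ≤ copies < 6), G5 (ratio < 2, copies < 4) —
a partition, verified exhaustively.  Resolution: G1 positive, G5 negative,
G2/G4 positive only with IHC 3+, G3 negative only with IHC 0/1+ (for 2+ or
3+ the amplified copy number carries the call — the guideline default; the
negative condition is the only one stated explicitly).  The ratio is
recomputed from the copy numbers; a supplied ratio disagreeing by more
than 1e-6 triggers a warning and the computed value wins.

## Evaluation

Multiclass metrics (accuracy, macro F1, Cohen's κ, generalized multiclass
MCC, macro precision/recall/specificity/Jaccard) are computed from the
confusion matrix; binary metrics add rank-statistic ROC AUC (ties halved).
Single-class inputs are flagged and κ/MCC reported as 0, AUC as NaN.
Inter-rater agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single rater — with the F-distribution 95 % CI; raters are
treated as a random sample of pathologists, which is an assumption, and
absolute agreement is what matters for an ordinal score.  Discordance
rates are percentages rounded half-up to two decimals.  A median-of-raters
utility forms consensus scores.  Cross-validation is stratified on the
joint (IHC class, FISH status) label — both heads need class coverage per
fold — by shuffling within each stratum and dealing round-robin with a
rotating starting fold (fold sizes differ by ≤ 1).  Aggregates are the
mean and *sample* standard deviation (n−1) over folds; FISH AUC is also
pooled over all held-out predictions.

## Synthetic data

The generator defines the study conditions for every test.

**Rendered tiles.**  Cells sit on a jittered grid (pitch 38 px, ~120 cells
per 512×512 tile); nuclei are hematoxylin discs (amount ≈ 0.8 ± noise);
membranes are DAB ring arcs of width ≈ 3 px whose arc fraction is the class
*completeness* and whose amount is drawn from the class range.  Class
defaults — 0/1+: amounts [0.1, 0.4], completeness 0.35; 2+: [0.5, 1.0],
0.65; 3+: [1.2, 2.0], 0.95 — encode the clinical phenotype (faint
incomplete → strong complete).  Mild Gaussian amount noise (σ 0.02–0.03)
is applied to stained pixels only.  Rendering goes through the forward
Beer-Lambert model, so the ground-truth mask and per-patch (A, F, L) are
exact by construction.  Slides add per-tile regional amount offsets
(`N(0, heterogeneity)`) and optional blank borders.

**Direct cohorts.**  For model experiments, GrayMaps are drawn directly:
an elliptical tissue blob on a 16×16 patch grid; a latent amplification
level `u ∈ [0,1]` sets the slide's base A and F inside the class range
(A ranges as above; F ranges 0.01–0.05 / 0.05–0.13 / 0.12–0.22); a smooth
4×4-upsampled regional field (sd 0.22) plus occasional focal hot spots
(probability 0.20 / 0.35 / 0 per class, staining one class up) create
intra-slide heterogeneity; L falls linearly with A (`97 − 22A` ± 1.5).
FISH labels are Bernoulli at per-class positive rates patterned on a
228-case clinical cohort — 2/26 for 0/1+, 53/157 for 2+, 45/45 for 3+ —
and FISH-positive slides draw `u` from the upper part of the range
(`U(0.40, 1)` vs `U(0, 0.80)`): gene amplification drives protein
expression, so within-class staining intensity correlates with FISH status.
Hot spots make the slide *maximum* an imperfect classifier while the full
map stays informative — the mechanism by which heterogeneous tumors defeat
a max-statistic baseline.

**FISH cases.**  (HER2, CEP17) pairs sampled per ASCO/CAP region with every
fifth case snapped just inside a decision boundary.

What the generator does **not** model: real tissue morphology (DCIS,
micropapillary or mucinous components, necrosis), nonspecific cytoplasmic
staining, scanner/illumination variation, and stain-vector drift.  Passing
tests therefore demonstrate correctness of the pipeline's computations and
the qualitative model ordering under controlled conditions — not clinical
performance on patient slides.

## Problem sizes and determinism

Experiments are sized for a single CPU: segmentation quality uses 60
rendered 256×256 tiles (20 per class); the cross-validation experiment
uses 120 synthetic slides (40 per class), 5 stratified folds, and the
reduced CNN geometry (the reproduction script trains at the desk default of
40 epochs; the in-suite experiment uses 20, which converges on most but not
all seeds — the ordering claim is most reliable at the default); the
capacity check overfits 8 slides for 300 epochs.  Every random draw flows from an explicit seed
(`numpy.random.SeedSequence`); k-means, fold assignment, training, and
inference are reproducible bit-for-bit given the seed, and inference is
augmentation-free by construction.

## Known limitations

* The CNN at desk geometry is far smaller than the reference ResNet18;
  conclusions about relative model ordering (map CNN vs GrayMax) transfer,
  absolute accuracies do not.
* Membrane completeness — emphasized by the ASCO/CAP guideline for 2+/3+
  discrimination — is represented only indirectly through F.
* k-means membrane selection can absorb cytoplasmic staining; the
  generator does not model that failure mode.
* Whole-slide pyramid formats (SVS/NDPI) are out of scope; inputs are RGB
  images or tile directories.
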