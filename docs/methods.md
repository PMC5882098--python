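# Methods

## The problem

End-stage heart failure leaves a histological signature in H&E-stained
myocardium: expansion of pale, collagen-rich stroma (fibrosis), loss of the
regular parallel packing of cardiomyocyte fibers, and enlarged,
hyperchromatic ("boxcar") myocyte nuclei. `hfhisto` implements a
weakly-supervised pipeline that turns those signatures into a patient-level
classification — failing vs non-failing heart — from nothing but tissue
images and per-patient labels, together with the statistics used to evaluate
it and an unsupervised consensus-clustering stage that can surface patients
whose tissue disagrees with their clinical label ("occult pathology").

Because the real whole-slide cohort is not required, the package includes a
first-class synthetic-cohort generator that reproduces the statistical
structure the analysis depends on; every stage is exercised end to end on
generated data.

## Pipeline

1. **Slide preparation** (`slide_prep`). Slides carry microns-per-pixel
   (mpp) metadata and are down-sampled by area averaging to the analysis
   resolution of 2.0 um/px (5x-objective equivalent). The tissue mask is
   Otsu's threshold on luma — implemented exhaustively over all 256 gray
   levels, maximizing between-class variance, lowest level on ties, tissue =
   the darker side — followed by removal of objects and holes smaller than
   0.1 mm². Manual border refinement is represented as an explicit add/remove
   edit layer so it is scriptable. Square ROIs (default 11 per slide,
   1250 px = 2.5 mm at 2 um/px) are drawn by seeded rejection sampling:
   pairwise non-overlapping, each at least 90% tissue (the `within the
   tissue border` requirement made testable); if the mask cannot hold the
   requested number, a capacity error reports how many were placed.

2. **Patching** (`patching`). 100 patches of 64x64 px (128x128 um) per ROI
   by default, at uniformly random offsets (overlap permitted — many tissue
   geometries cannot hold 100 disjoint patches). Every patch carries its
   patient's cohort label: supervision is weak, at the patient level.
   Training sets are augmented with the four right-angle orientations (x4);
   augmentation is never applied at inference.

3. **CNN arm** (`cnn`). A compact fully-convolutional network:
   64x64x3 -> [3x3 conv 16, BN, ReLU, 2x2 max-pool] -> [3x3 conv 16, BN,
   ReLU, pool] -> [3x3 conv 24, BN, ReLU, pool] -> [3x3 conv 28, BN, ReLU]
   -> 4x4 conv to 2 channels (+bias) -> softmax. Convolutions followed by
   batch norm are bias-free. The layout has 13,306 learnable parameters
   (closed form: 432+32, 2304+32, 3456+48, 6048+56, 896+2), a natural
   stride of 8, and maps a 64-px input to exactly one output location, so a
   trained patch classifier applied to a whole ROI yields a dense
   failing-probability map whose entries provably equal the corresponding
   64-px sliding-window crops (tested at random positions). The 28-channel
   stage-4 / 4x4 head pairing was chosen to satisfy the 1x1-map property
   while staying in the published "approximately 13,500 parameters" band.

   Layers, backpropagation and SGD are implemented directly on numpy
   arrays in float32. Convolutions run as k*k shifted GEMM accumulations
   (BLAS matrix products over the full input per kernel offset), which on a
   single CPU core outperforms explicit im2col for these channel widths;
   max-pool backward routes gradients to the first maximum (deterministic
   subgradient). Gradient correctness is verified against finite
   differences on a kink-free (conv+BN) configuration.

   Training: softmax cross-entropy, SGD with momentum 0.9, weight decay
   5e-4 on convolution weights, learning rate 0.01 with a x0.1 step at
   epoch 20; defaults 30 epochs at the fixed batch size of 64. With a
   validation set, the best-validation-epoch weights are retained.
   Training is deterministic for fixed seeds under single-threaded BLAS.

4. **Engineered-feature arm** (`charm_baseline`). A deterministic bank of
   287 named features per ROI: pixel moments and quantiles, 13 Haralick
   co-occurrence statistics (32 gray levels, 4 offsets averaged), uniform
   LBP histograms at radii 1 and 2, edge statistics and Fourier-magnitude
   moments — each on grayscale and on each RGB channel — plus gray-only
   Gabor energies (4 frequencies x 4 orientations), Zernike moment
   magnitudes to order 8, and Chebyshev coefficient energies to order 20.
   This is a documented, unit-tested subset in the WND-CHARM spirit; 4059-
   feature parity is a non-goal. Features are z-scored with training-set
   statistics, the top 20 are selected by greedy mRMR (MID difference
   criterion, mutual information on tercile-discretized values split at
   mean +/- sd/2, ties to the lowest index; Wilcoxon and Fisher-score
   selectors are available behind a flag), and a 1000-tree random forest
   (bootstrap bagging, sqrt(p) features per split, trees grown to purity)
   emits the image-level failing probability as its tree-vote fraction.

5. **Aggregation and evaluation** (`aggregate_eval`). An image is called
   failing when its probability strictly exceeds 50%; the patient
   probability is the fraction of failing image calls; the diagnosis is the
   strict majority (a probability of exactly 0.5 resolves to non-failing;
   with 11 images no tie occurs). Metrics: confusion counts, accuracy,
   sensitivity, specificity, PPV (empty denominators surface as NaN with a
   warning, never as 0), ROC/AUC over all score thresholds, Cohen's kappa
   with marginal-product chance correction. Statistical comparisons:
   pooled-variance unpaired t-test, one-sample t-test, and the two-sample
   Kolmogorov-Smirnov test; "comparing ROC curves by KS" is
   operationalized as KS on TPR values interpolated onto a common
   1001-point FPR grid — statistically unconventional, implemented as
   stated. Splits are patient-level and label-stratified: floor(n/2)
   patients train (209 -> 104/105) and 3-fold cross-validation on the
   training half; every run asserts that no patient crosses a boundary.

6. **Consensus clustering** (`consensus_clustering`). Image-level feature
   vectors are z-scored; each of (default) 500 resamples draws 80% of items
   without replacement and clusters them by average linkage on Euclidean
   distance; the dendrogram is cut at every candidate k (default 2..6, one
   linkage per resample). Consensus(i,j) = co-clusterings / co-inclusions;
   never-co-included pairs are recorded missing and excluded from CDFs.
   k is chosen where the consensus-CDF area plateaus: the smallest k whose
   next relative delta-area falls below 0.10. Two calibration notes, both
   measured on planted Gaussian mixtures: (i) a 0.05 threshold sits inside
   the noise band created by the instability of forced extra splits of
   homogeneous clusters (relative gains up to ~0.06), so the default is
   0.10, between that noise and the >= ~0.2 gains of genuine structure;
   (ii) with no structure at all the first split explains almost nothing
   (A(2) <= ~0.11 vs >= ~0.38 for genuine mixtures) and relative deltas are
   dominated by a near-zero denominator — the known null pathology of
   consensus clustering — so an area floor of 0.2 returns k_min in that
   case. Patients labeled non-failing whose images majority-assign to a
   failing-majority cluster or to a cluster with no label majority are
   flagged as discordant.

7. **Orchestration** (`pipeline`, `hfhisto` CLI). One config drives cohort
   -> split -> fold loop -> retrain-on-full-training -> held-out evaluation
   -> CSV/JSON reports; the run manifest stores the config hash and all
   seeds, a partial run with a drifted config is refused, and metrics can
   be recomputed under the pathology-revised label schema (v2) without
   retraining. CLI verbs: `simulate`, `prepare`, `train`, `evaluate`,
   `cluster`, `relabel`, `report`, `run-all`.

## The synthetic cohort

`generate_tissue_image` renders a square tissue tile as: oriented
sinusoidal fiber banding (eosin pink, 16-um period) whose phase coherence
degrades with `fiber_disruption`; pale collagen-like stroma from a
thresholded smooth blob-noise field, iteratively calibrated so the rendered
stroma-pixel fraction tracks `fibrosis_fraction` (perivascular cuffs around
small vessels are always present, ~0.5% area); and Poisson-scattered
elliptical hematoxylin nuclei oriented along the local fiber direction,
whose size and darkness scale with `nucleus_scale`. Every raster is a pure
function of (parameters, side, mpp) including the seed.

Class presets at 2 um/px: non-failing (stroma 0.05, 600 nuclei/mm², scale
1.0, disruption 0.10) and two failing severity tiers — moderate (0.22, 560,
1.45, 0.35) and severe (0.40, 520, 1.90, 0.60) — reflecting the spectrum of
pathology across ischemic and non-ischemic cardiomyopathy in a real failing
cohort; failing patients split evenly between tiers. `effect_size`
(strong/moderate/weak = 1.0/0.45/0.18) scales the failing deltas toward the
non-failing anchor. Per-patient and per-ROI jitter (sd 0.03 on the stroma
fraction, plus nucleus/disruption jitter) emulates biological and sampling
variability; it makes a fixed stroma-fraction discriminator's accuracy
strictly increase across weak < moderate < strong, as asserted in tests.
Occult-pathology patients carry the non-failing clinical label (schema v1)
over severe-tier tissue, and move to the failing class under the
pathology-revised schema v2. Cohorts have exact class counts
(round(n x proportion)); cohort ROIs are rendered lazily from stored
per-ROI parameter recipes, so an 80-patient cohort costs no persistent
raster memory.

What the generator does **not** model: stain variability and scanner
artifacts, immune infiltrates, myocyte disarray at the single-cell level,
spatially correlated disease (each ROI is an independent draw of the
patient's severity), and any photorealism. Passing tests therefore
demonstrate that the pipeline machinery — masking, sampling, learning,
aggregation, selection, clustering, bookkeeping — behaves correctly on data
with the assumed statistical structure; they say nothing about accuracy on
real tissue.

## Problem sizes used

The texture model is stationary, so the discriminative content of a patch
does not depend on how large its source ROI is; desk-scale runs therefore
shrink ROI side and training length rather than the cohort structure.

* Acceptance script (`scripts/acceptance.py`): 80 patients (40/40
  label-stratified split), 11 ROIs per patient at 512 px, 25 patches per
  ROI with x4 rotation augmentation (44,000 training patches), 3 epochs of
  SGD at batch 64, then dense-map evaluation of all 440 test ROIs.
  Strong-effect separation; sensitivity/specificity are reported in percent
  on the 40 test patients.
* The test suite's headline fixture uses the same 80-patient design at
  320-px ROIs with 6 patches per ROI and 3 epochs; the
  ordering benchmark (CNN vs forest) uses 16-patient moderate-effect
  cohorts over 3 seeds; the clustering benchmark uses a 24-patient cohort
  (2 occult) at 224-px ROIs, 250 resamples.

## Numerical and design notes

* Strict ">" at both decision thresholds; channel 1 is the failing class
  everywhere; coordinates are row-major, 0-based, half-open.
* Otsu ties break to the lowest gray level; the implementation is the
  exhaustive argmax and is tested against an independent brute-force loop.
* The reference CNN differs from a literal reading of one published layout
  (32-channel stage 4 with a 3x3 head): that layout maps a 64-px input to a
  2x2 output, which contradicts the one-probability-per-patch training
  semantics; the 28-channel/4x4 variant preserves the parameter budget and
  the stride and restores the 1x1 mapping.
* mRMR discretization (terciles at mean +/- sd/2) and the MID criterion are
  the package's operationalization; the selection is tested against
  exhaustive greedy enumeration on small problems.
* Feature standardization precedes mRMR and the forest; test-set transforms
  reuse training statistics exactly.
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `InvalidArgumentError`, `CapacityError`, ...) rather than returning
  silent defaults; undefined metric ratios are NaN with a warning.
* Known limitations: consensus clustering on structureless data is handled
  by the area floor described above rather than by a significance test;
  the KS-on-ROC comparison inherits the original analysis's unconventional
  construction; the CNN runs on CPU only and at desk scale; `files` mode
  (reading an on-disk cohort manifest) is limited to the CLI `prepare`
  verb — full experiments run on synthetic cohorts.
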