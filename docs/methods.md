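# Methods

## Scope and model

`gliopipe` implements a digital-pathology grading pipeline for diffuse
gliomas that integrates three information sources, following the post-2016
practice of combining histology with molecular markers:

1. **image appearance** of H&E-stained tissue (patches of a
   1000×1000-pixel region of interest in the full-scale protocol),
2. a **4-marker molecular profile** — IDH mutation (MT/WT), ATRX mutation
   (MT/WT), 1p/19q codeletion (CD/NC), MGMT promoter methylation (ML/UM) —
   encoded as binary indicators with MT/CD/ML = 1, and
3. **cellularity**, the fraction of tissue area covered by (optionally
   dilated) segmented nuclei, a proxy for tumor cell density.

Three-way grading (LGG II, LGG III, HGG IV) is cascaded into two binary
steps: a plain CNN separates HGG from LGG, and a deeper residual network
separates LGG II from III, on the premise that adjacent lower grades differ
more subtly and benefit from extra depth. Both stages fuse the molecular
vector and the cellularity scalar into the first dense layer.

## ROI selection

Whole slides are reduced to a thumbnail, over-segmented with SLIC
(default 400 superpixels, compactness 10), and superpixels are ranked by
mean luma (Rec. 709 weights). Dense cellular tissue absorbs more light, so
the candidates at or below the 10th-percentile mean intensity are kept
(inclusive quantile; ties broken by larger area, then lower label id).
Near-saturated superpixels (mean > 240) are dropped first as glass: the
low-intensity ranking presupposes tissue, and glass is brighter than any
tissue. Nothing is ever excluded for being dark — which is exactly why a
pen-marker stroke, darker than any tissue, hijacks the ranking. This
failure mode is reproduced deliberately by the synthetic slide generator;
the mitigation is a user-supplied exclusion mask, not automatic ink
detection.

## Stain model and normalization

Transmitted intensity follows Beer–Lambert: `I = I0 · exp(−X)` with
`I0 = 255`. The OD image `X` (3 × n_pixels, intensities clipped to ≥ 1
before the log so OD is finite) is factorized as `X ≈ W L` with
nonnegative, unit-norm color-appearance columns `W` (r = 2 stains) and
nonnegative densities `L`, minimizing
`½‖X − WL‖²_F + λ Σ_j ‖L(j,:)‖₁` (λ = 0.1).

Numerical choices:

* **Solver.** Alternating convex updates, each a guaranteed-descent step,
  so the objective is monotone non-increasing (asserted in tests):
  coordinate-descent nonnegative lasso for `L` rows; projected gradient
  with a Lipschitz step for `W` on the set {w ≥ 0, ‖w‖₂ ≤ 1} (projection =
  clip to the nonnegative orthant, then rescale into the unit ball).
  Up to 200 alternations, stop at relative objective change < 1e-6.
* **Initialization.** `W` starts at the Ruifrok–Johnston H&E reference
  vectors, hematoxylin (0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11);
  extra columns (r > 2) start uniform-random.
* **Fitting set.** `W` is fitted on ≤ 20 000 tissue pixels (OD norm above
  0.15), subsampled with the config seed; densities are then re-solved for
  every pixel.
* **Debiasing.** The densities actually applied to pixels are re-solved
  with λ = 0 at the fixed `W` (standard lasso debiasing), warm-started
  from the clipped least-squares projection. Without this, the L1
  shrinkage systematically brightens reconstructions by ~10 gray levels
  and self-normalization would not return the input.
* **Stain labeling.** The NMF permutation is fixed by assigning the two
  columns to (hematoxylin, eosin) via the pairing with the larger total
  cosine similarity to the Ruifrok references. Simple channel-ratio rules
  were rejected: a perturbed eosin vector with near-zero blue absorbance
  makes any red/blue ratio test unstable.

Normalization to a target image rescales each source density row by the
ratio of target to source **pseudo-maxima** (the 0.99 quantile of the row,
linear interpolation), then recombines with the *target's* `W` and
exponentiates. The orientation of the rescaling (multiply by target,
divide by source) is pinned down by the row-scaling law checked in the
acceptance tests: after normalization, a fresh stain fit of the normalized
signal reproduces the target's pseudo-maxima. Glass pixels carry no
density (L ≈ 0) and therefore stay white.

## Nuclei segmentation

Two interchangeable backends produce binary nuclei masks:

* **Classical (default for pipeline runs; deterministic).** Stain-separate
  the image, threshold the hematoxylin density map, fill holes, remove
  objects under 10 px, and split touching nuclei by distance-transform
  watershed for instance counts. The threshold is an Otsu seed refined by
  a few intermeans iterations; the refinement matters on synthetic images
  whose near-noiseless background collapses into a single histogram bin,
  where the binned Otsu cut can land inside the background cluster.
  With no subsampling (images up to ~20 000 tissue pixels) the backend is
  permutation-invariant, hence exactly equivariant to 90° rotations.
* **Trainable.** A U-Net-style encoder–decoder (default 4 levels; tests
  use a reduced depth-3, width-8 variant) with 2-channel softmax output,
  trained with per-pixel cross-entropy (mean over pixels and batch — the
  summation convention is not otherwise pinned down), Adam at
  `lr0 = 0.001`, minibatch 2, and the polynomial schedule
  `lr_i = lr0 · (1 − i/N)^0.9` over `N = 80` epochs (N = 15 at desk
  scale). Inputs are standardized with fixed brightfield constants
  (mean 0.7, spread 0.25 of the [0,1] scale); with raw uncentered inputs
  the short desk-scale training is fragile to initialization.
  The network core is a small in-package CPU implementation
  (im2col convolutions, explicit backprop, Adam) — adequate for the
  desk-scale problem sizes this package targets.

Training data is any collection of paired RGB tiles and binary masks, such
as the public multi-organ nuclei-annotation corpora used for the
full-scale protocol, or the synthetic tiles generated here.

## Cellularity

`cellularity = foreground / total` after optional morphological dilation
of the mask, motivated by the cytoplasm surrounding each nucleus.
Surveyed diameters: 0 (none), 10–15; 11–12 recommended. The structuring
element is a disk of the given diameter (shape configurable to square);
even diameters are reduced by one so the footprint stays centered — noted
in the log. Dilation only adds pixels, so cellularity is non-decreasing in
the diameter (property-tested, and checked exactly against a brute-force
neighborhood-max oracle). Per-case cellularity is the mean over the case's
ROIs (one ROI per case in the standard protocol). All segmented nuclei
count toward the statistic; no benign/malignant discrimination is
attempted, consistent with a generic nuclei segmenter.

## Cascaded classifier

* **Patches.** ROIs are tiled with `ceil(dim/512)` evenly spaced 512 px
  windows per axis, so a 1000×1000 ROI yields a 2×2 grid at stride 488
  (windows overlap when 512 does not divide the ROI).
* **Augmentation** (training only, fresh each epoch): rotation ∈
  {0°, 90°, 180°, 270°}, flip ∈ {none, horizontal, vertical}, scale
  uniform in [0.95, 1.1] with center crop/pad back to size.
* **Architectures** (desk-scale defaults; depth/width configurable):
  stage 1 is four 3×3 conv blocks with 2×2 max-pooling and global average
  pooling; stage 2 is a residual network with six identity-skip blocks —
  deeper than stage 1 by construction. Patches are resized to 48×48 and
  standardized with fixed brightfield constants (mean 0.7, spread 0.25 of
  the [0,1] intensity scale). Fusion concatenates the molecular vector
  (4 indicators + 4 missingness bits) and cellularity to the pooled image
  features before the first dense layer; each block can be ablated. The
  cellularity scalar is likewise standardized with fixed constants
  ((c − 0.25)/0.1): as a raw value its ~0.1 dynamic range is numerically
  invisible next to the binary indicators, and the network would learn to
  ignore its own most informative covariate.
* **Training.** Adam, lr 2e-3, batch 12, 25 epochs — enough optimization
  steps for the small cohorts used here; all randomness flows from one
  config seed.
* **Decision rule.** Case-level mean of patch probabilities, threshold
  0.5, ties to the *higher* grade (clinically conservative); an HGG
  verdict short-circuits stage 2.
* **Cross-validation** is stratified by grade at the case level (8:2
  train/test per fold at k = 5); no patch of a test case is ever seen in
  training. Reports give per-fold accuracies, mean ± sample standard
  deviation (ddof = 1), and a fold-accumulated confusion matrix.
* **Molecular classification** (the reverse task: predicting IDH, 1p/19q
  or ATRX status) uses a small feed-forward network (one hidden layer of
  16, L-BFGS) on standardized tabular features — per-channel ROI
  mean/std, nuclei count, mean nucleus area, cellularity, one-hot
  histology and grade — with repeated stratified 5-fold CV (10 repeats by
  default; the repeat count is a free parameter).

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed and defines its study conditions.

* **H&E tiles.** Elliptical nuclei (uniform rejection placement, overlaps
  allowed unless disabled; at most 100 attempts per nucleus, and an error
  if expected coverage would exceed 95%) assign a high hematoxylin density
  (~0.75–1.05) against a smooth eosin stroma field; the OD field is
  exponentiated through Beer–Lambert at I0 = 255 and quantized to 8 bits.
  The default stroma transmission is 215 — visibly pink stroma whose OD
  (~0.17) sits above the tissue threshold, as real stained stroma does.
  Stain-vector perturbation (random rotation/scaling) emulates
  scanner/stain variability. The exact mask, density fields and ellipse
  layout are returned for oracle tests.
* **Mock slides.** Bright glass (~250), dark speckled tissue discs, and an
  optional near-black polyline pen stroke 15 px wide kept disjoint from
  tissue — wide and dark enough to dominate the intensity ranking, which
  is the documented ROI failure mode.
* **Cohorts.** Grade-conditional nuclei density (nuclei/px², mean ± sd):
  II 0.004 ± 0.0008, III 0.008 ± 0.0010, IV 0.012 ± 0.0015 on 96×96 ROIs
  with 2.5–5 px nuclei — chosen once to give mean cellularities of roughly
  0.15 / 0.29 / 0.39, i.e. the monotone grade–cellularity relationship at
  comfortably separable but overlapping spreads. Molecular priors per
  grade (P of IDH MT / ATRX MT / 1p19q CD / MGMT ML): II 0.80/0.55/0.40/0.70,
  III 0.75/0.55/0.35/0.60, IV 0.10/0.15/0.02/0.45, following the broad
  epidemiology of diffuse gliomas (IDH mutation common in lower grades and
  rare in primary glioblastoma; codeletion essentially absent in GBM).
  Grade IV cases are GBM; codeleted LGG cases are labeled
  oligodendroglioma, the rest astrocytoma/oligoastrocytoma.

Passing tests on these data show that the algorithms recover structure the
generator encodes (density → darkness → grade; priors → marker–grade
association). They do not show robustness to what the generator omits:
real chromatin texture, touching/overlapping nuclei clusters at high
density, necrosis, microvascular proliferation, scanner noise, or
out-of-focus regions. Full-scale cohort accuracies on real slides are
out of scope here, and desk-scale results do not transfer to them.

## Problem sizes

Defaults in the test-suite and the acceptance script are desk-scale by
design: 150-case cohorts (50 per grade), 96×96 ROIs resized to 48×48 for
the classifiers, 5-fold CV, a depth-3 width-8 segmentation net trained 15
epochs on eight 64×64 tiles. All are configuration parameters; the
full-scale protocol values (1000×1000 ROIs, 512×512 patches, 80 epochs,
batch 2) remain the documented defaults of their respective configs.

## Known limitations

* The NMF stain model assumes exactly two dominant stains; r > 2 is
  supported but unvalidated beyond residual-nesting checks.
* The classical segmenter has no instance-level notion of overlapping
  nuclei beyond watershed splitting; heavily confluent tissue will
  under-count.
* Pen-mark handling is manual by design (exclusion mask); there is no ink
  detector.
* The in-package NN core is single-threaded NumPy: appropriate for the
  desk-scale networks here, not for 512×512-patch training at cohort
  scale.
* Pyramidal WSI formats are supported only through pre-extracted PNG/TIFF
  images; no slide-server backend is bundled.
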