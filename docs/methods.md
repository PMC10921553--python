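# Methods

`cbctomics` implements a paired planning-CT (pCT) / cone-beam-CT (CBCT)
radiomics-concordance study as a tested, seedable pipeline.  Because no
patient data are distributed with the package, every stage is exercised on
synthetic paired phantoms whose statistical structure mirrors what the
analysis assumes; the phantom generator is first-class, tested code, not a
fixture.

## Synthetic paired phantoms

A phantom is a soft-tissue background — Gaussian noise low-pass filtered to a
4 mm correlation length, rescaled to a 10 HU standard deviation around a
30 HU tissue mean — containing one tumor: the union of a random ellipsoid
(base radius 8–15 mm, per-axis eccentricity 0.75–1.25) and a few spherical
lobes seated on its surface (default 4 lobes, amplitude 0.3 of the base
radius).  Tumor voxels are brightened by a contrast drawn from 20–60 HU;
the rasterised indicator is smoothed by half a voxel before being added, as
a stand-in for partial-volume edges.  The tumor is brighter than tissue by
construction; real polarity is irrelevant to the pipeline's mathematics and
a single polarity keeps CLAHE and the segmentation loss consistent.

The default grid is 48×48×48 voxels at (1, 1, 5) mm — 5 mm slices as on a
planning CT.  The CBCT-like counterpart of each phantom is derived
deterministically from the same anatomy by:

1. resampling the slice axis to the native 3 mm CBCT spacing;
2. scaling contrast about the tissue mean (default factor 0.7);
3. multiplying by a separable cosine shading field (default amplitude 0.15),
   mimicking cupping;
4. adding white noise (default sigma 15 HU, versus the ~10 HU background
   texture of the pCT);
5. resampling back to the 5 mm pCT grid, the mask travelling by
   nearest-neighbour.

Degradation magnitudes are free parameters of the generator, chosen once at
values typical of the qualitative pCT/CBCT gap (roughly tripled noise, a
third of the contrast lost, ±15 % shading); they are not estimates of any
particular scanner.  Per-case seeds are `master seed + case index`, so
cohorts are reproducible and cases independent.

What the phantoms deliberately do not model: projection/reconstruction
physics, scatter and streak artifacts, anatomy outside the tumor
neighbourhood, organ motion, and inter-observer contour variability.
Passing tests on phantoms therefore demonstrate that the pipeline's
machinery is correct and well-conditioned — not that any clinical
performance level transfers to patients.

## Preprocessing

The chain is window → crop → resample → CLAHE, all deterministic:

* **Windowing** clamps to (−200, 300) HU, the soft-tissue range.
* **Cropping** takes the bounding box of the mask (when given) or of voxels
  above the window floor, expanded by a 2-voxel margin; the box is recorded
  so masks can be mapped back for scoring in original geometry.  A
  `crop_mode="intensity"` switch forces the intensity box even when a mask
  is available, keeping training and inference crops consistent on phantoms
  whose whole grid is informative.
* **Resampling** is a separable, half-sample-aligned linear resize to a
  fixed grid (masks use nearest-neighbour); spacing is rescaled so the
  physical extent is preserved.  The full-scale profile targets
  256×256×128; the scaled profile 48×48×48.
* **CLAHE** operates per axial slice on the window-normalised image: the
  slice is tiled (default 8×8; 4×4 in the scaled profile, keeping ~150
  pixels per tile), per-tile histograms (256 bins) are clipped at
  `clip_limit × tile pixels` (default 0.01, i.e. ≈2.5× the uniform level)
  with the excess redistributed uniformly, tile CDFs become the mappings,
  and mappings are blended bilinearly between tile centres.  Output is
  rescaled to the HU window, so enhanced images remain valid windowed CT.
  CLAHE is applied slice-wise, not as a 3D operator, matching the standard
  formulation.  CLAHE feeds the network only; radiomics are extracted from
  the raw windowed image by default (`radiomics_on_raw`), the convention of
  standard feature extractors that operate on calibrated HU.

## Segmentation network and loss

A 3D U-Net with residual blocks, implemented directly on numpy with
numba-compiled 3×3×3 convolution kernels and hand-written backward passes.
Layout is channels-major `(C, N, X, Y, Z)` float32.  Architecture, per
level `i` with width `base × 2^i`:

* encoder: residual block (conv–instance-norm–ReLU ×2 with identity skip,
  1×1×1-projected on width change), then 2× max-pool;
* decoder: 2× trilinear upsample (half-voxel aligned) + 1×1×1 width
  reduction, concatenation with the encoder feature, a 1×1×1 fusion back to
  the level width, then a residual block — the fusion keeps the expensive
  full-resolution 3×3×3 convolutions at base width;
* head: 1×1×1 convolution + sigmoid, one channel.  The decoder fusion and
  head are deliberately free of extra normalisation: under short training
  schedules additional instance norms in the decode path measurably slowed
  convergence of the Tversky loss, whose optimum needs a strongly negative
  mean logit on imbalanced volumes.

The loss is `1 − T(α, β)` with

    T = Σ p·g / (Σ p·g + α Σ p·(1−g) + β Σ (1−p)·g),

ε = 1e-6 added to numerator and denominator (the index is undefined when
prediction and mask are both empty).  Defaults α = 0.3, β = 0.7 — the
established setting that penalises false negatives harder, suited to small
lesions; α = β = 0.5 recovers soft Dice exactly.  Optimisation is Adam at
learning rate 1e-4; 150 epochs at batch 2 at full scale.  The scaled
profile (15 epochs) uses batch size 1 — twice the update steps within the
fixed epoch budget at identical cost — and pools only in-plane at the
first level ((2,2,1), then (2,2,2)): at (1, 1, 5) mm spacing a tumor spans
only a few slices, and keeping slice-axis resolution through the first
level is the standard anisotropic-grid heuristic.  Random flip
augmentation is available but off by default: at short step budgets it
slows convergence more than it helps generalisation.  One network is trained per modality (a joint-training flag exists
on the pipeline functions by passing merged cohorts).  Training is fully
seeded: weight init from the network seed, data order from the training
seed; repeated runs are bitwise identical.

## Segmentation metrics

DSC = 2|P∩G|/(|P|+|G|), defined as 1.0 when both masks are empty (the
degenerate case is unspecified in common usage; agreement is rewarded).
Surfaces are face-connected boundary voxels (a mask voxel with a background
6-neighbour, grid boundary counting as background).  Distances are
Euclidean between voxel centres in mm.  HD95 is the maximum of the two
directed 95th percentiles — one of the common direction-combining
conventions, recorded here explicitly.  ASSD averages both directed
distance sets.  All three are verified against exhaustive O(n²) brute-force
oracles on random mask pairs to 1e-9.  Scoring happens in the original
image geometry after inverting crop and resample.

## Radiomic features

The engine computes, from scratch, the standard published feature
definitions: 19 first-order features; GLCM (24, symmetric, distance 1, 13
directions merged into one matrix), GLRLM (16, 13 directions merged),
GLSZM (16, 26-connected zones), GLDM (14, α = 0, centre counted in the
dependence), NGTDM (5, 26-neighbour means); and 14 shape features (voxel
volume, marching-cubes surface area with a half-voxel indicator smoothing
and an isoperimetric floor so sphericity never exceeds 1, PCA axis lengths,
hull-accelerated maximum diameters, Compactness1 — Compactness2 and
spherical disproportion are omitted as monotone functions of sphericity).
Discretisation is min-referenced fixed-bin-width binning (default 25 HU).
Degenerate definitions return documented values: GLCM correlation and MCC
are 1 on a constant region, NGTDM coarseness is 1e6 when the denominator
vanishes.

Derived images: four monotone intensity transforms (square, square root,
logarithm, exponential) on the unit-rescaled volume, mapped back to the
input span so one bin width fits every image type; gradient magnitude in
HU/mm; scale-normalised, spacing-aware Laplacian of Gaussian (per-axis
second derivatives over squared spacing, mean-subtracted input); and the 8
sub-bands of a single-level stationary coif1 wavelet decomposition,
sub-band letters following the (x, y, z) axis order (HLH = high-pass x,
low-pass y, high-pass z).

The default manifest emits exactly 1037 features per image, decomposed
14 shape / 19 first-order / 172 texture / 728 wavelet / 104 LoG.  No single
canonical extractor configuration yields that printed inventory, so the
packaged manifest declares a composition that reproduces the counts
exactly (see `radiomics/manifest.py`): texture = 75 matrix features on the
original image + first-order on the four intensity transforms + GLRLM and
NGTDM on the gradient image; wavelet = 8 × (16-feature first-order subset +
75 matrix features), the subset omitting Minimum/Maximum/Range whose values
on filtered images are dominated by isolated filter-response peaks; LoG =
GLCM at σ = 1, 2, 3 mm plus GLRLM at σ = 1, 2 mm.  The composition lives in
the manifest, not the extractor, and alternative manifests are ordinary
data.

## Concordance analysis

For each feature, Pearson R across the paired cohort (population moments —
the sample/population distinction cancels in R).  Features with zero
variance in either table are reported as missing, never silently dropped,
and never selected.  A feature is interchangeable between modalities when
R strictly exceeds 0.9.  No multiple-testing correction is applied: the
rule is a plain threshold on R, not a hypothesis test; per-feature
two-sided p-values are annotated for reference only.  Three literature
prognostic features (original first-order Energy, original and wavelet-HLH
GLRLM gray-level non-uniformity) are flagged when selected.  R is computed
on raw feature values; being scale- and shift-invariant, normalisation
could not change it.

## Scaled study profile and problem sizes

The package's desk-scale study — used by the test suite and
`scripts/acceptance.py` — generates 60 paired phantoms at 48³, splits 70/30
(so 42 train / 18 test; a 103-case split reproduces the 30-case test-set
arithmetic), trains depth-3/width-8 networks for 15 epochs per modality,
and scores the held-out cases in original geometry.  Cohort-level
concordance checks use a reduced first-order manifest at n = 20 so the
monotonicity of R against CBCT noise is measured across three noise levels
quickly.  These sizes are the package's own scaled profile; the full-scale
profile (256×256×128, depth 4, width 16, 150 epochs, n = 103) is selected
by configuration.

## Numerical and design notes

* Convolution backward-input reuses the forward kernel with flipped,
  channel-transposed weights; the weight gradient has a dedicated
  single-pass kernel.  Gradients of every layer are verified against
  central differences.
* The trilinear 2× upsampling is implemented by closed-form slice
  arithmetic; its backward pass is the exact transpose (adjoint-tested).
* Instance-norm statistics use an einsum second moment; ε = 1e-5.
* The empty-prediction case in evaluation is flagged per case with DSC 0
  and missing distances rather than aborting the cohort.
* Known limitations: phantoms are far easier to segment than rectal tumors
  (no confounding anatomy), so absolute DSC levels here exceed clinical
  ones; the concordance analysis shares ground-truth masks between
  modalities unless network masks are substituted, isolating image — not
  contour — variability.
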