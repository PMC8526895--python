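# Methods

`habitatrad` implements intratumoral habitat imaging for co-registered
FDG-PET/CT with downstream radiomics modeling.  This note records the
models, the defaults and why they were chosen, what the synthetic
phantoms do and do not emulate, and the numerical conventions.

## Preprocessing

Inputs are NIfTI PET, CT and binary lesion-mask volumes assumed
co-registered.  The canonical representation is:

* **PET in SUV.**  Body-weight SUV: `SUV = C_act [Bq/mL] * w [g] / D [Bq]`,
  with the injected dose assumed decay-corrected to scan start upstream
  (recorded in the preprocessing log).  Lean-body-mass or BSA
  normalization is not implemented; the normalization used is stored in
  the provenance dictionary of every `VoiPair`.
* **CT windowed by clipping.**  The default window (width 1,140 HU,
  level −380 HU) spans the union of the lung window (700/−600) and the
  mediastinal window (300/40), i.e. [−950, 190] HU.  Windowing clips
  without rescaling so HU semantics — and hence the fixed 25-HU
  discretization downstream — are preserved.  Windowed CT is used for
  both habitat generation and feature extraction (configurable).
* **1 mm isotropic grids.**  Intensities are resampled trilinearly,
  masks nearest-neighbour.  Internal axis order is (z, y, x), 0-based.

## Habitat generation

Three methods partition each lesion:

**Adapted clustering.**  A 4-channel feature hypervolume (PET SUV, CT
intensity, PET local entropy, CT local entropy) is built over the mask's
bounding box.  Local entropy is the Shannon entropy (bits) of a 32-bin
equal-width histogram over each voxel's 9×9×9 neighbourhood; the bins
span the masked intensity range and, when a mask is supplied, only
masked neighbours are counted, so the texture estimate describes the
lesion rather than the adjacent background.  Each lesion is clustered
(k-means, Euclidean, k-means++ with 10 restarts, seeded) into
supervoxels whose count adapts to lesion volume:
`k_sv = max(1, round(V / 729 mm³))` — every supervoxel aggregates a
comparable physical volume regardless of lesion size.  Channels are
normalized to [0, 1] by cohort-wide masked min/max (stats retained so
new lesions can be mapped onto the same scale).  Supervoxel centroids
(member means) from all lesions are then clustered for k = 2..10 and the
habitat count is chosen by the Calinski–Harabasz index (ties broken
toward smaller k; candidate k values not below the supervoxel count are
skipped with a log entry).  Habitat indices are sorted by ascending mean
PET SUV of their centers, so the top index is always the
highest-uptake signature.  Spatial contiguity is deliberately not
enforced: clustering acts on feature vectors only, with the entropy
channels carrying spatial context implicitly.

**Conventional clustering.**  Identical two-stage scheme, but every
lesion gets the same fixed supervoxel count (default 50, configurable)
and channels are normalized per voxel by the min/max of its own 9×9×9
neighbourhood (constant neighbourhoods map to 0).

**Otsu intersection.**  Per lesion, Otsu thresholds are computed on the
masked PET and CT values independently (exhaustive search over midpoints
between consecutive distinct values, maximizing between-class variance —
equivalent to, and tested against, a brute-force oracle).  The four
intersections are coded 1 = PET low ∩ CT low, 2 = PET low ∩ CT high,
3 = PET high ∩ CT low, 4 = PET high ∩ CT high.  Codes are fixed even
when an intersection is empty.  Thresholds are per-lesion, never
cohort-level.  Lesions with a constant masked channel are rejected.

Degenerate lesions (< 2 masked voxels) are rejected at load time.

## Feature extraction

Per region (whole lesion or one habitat) and per modality, exactly 929
named features; 1,858 over PET+CT.  Missing values are allowed, missing
columns are not.

* **Base set (107).**  18 first-order + 14 shape + 24 GLCM + 16 GLRLM +
  16 GLSZM + 5 NGTDM + 14 GLDM, with the standard radiomics naming.
  Discretization uses a fixed bin width anchored at the region minimum —
  25 HU for CT, 0.25 SUV for PET — which makes texture matrices
  invariant to intensity shifts.  GLCM and GLRLM aggregate over the 13
  unique 3-D directions; GLSZM zones and GLDM dependencies use
  26-connectivity; GLDM dependence uses α = 0 (equal levels) and counts
  the centre voxel.  Shape features are computed on the region's own
  geometry from a marching-cubes mesh of the lightly smoothed mask
  (σ = 0.8 voxels, suppressing the voxel staircase that would bias
  surface area upward); principal-axis lengths come from the physical
  coordinate covariance.  Texture families of single-voxel regions are
  NaN, never silent zeros.
* **CoLIAGe (390).**  Per voxel, the dominant local gradient orientation
  is the principal eigenvector of the structure tensor box-summed over a
  sliding window; its polar angle (folded to [0, π/2]) and azimuth
  (folded to [0, π)) are quantized into 8 bins.  Within-window
  co-occurrence matrices of the quantized orientations (three axis
  offsets, symmetric, truncated at the boundary) are summarized by 13
  Haralick-type measures per voxel, and each measure map by 5 region
  statistics: 13 × 2 angles × 3 windows (3, 5, 7) × 5 stats = 390.
  Zero-gradient voxels map to a single symbol, so constant regions give
  exactly zero entropy-type values.  Regions narrower than the smallest
  window are missing with a logged reason.
* **Wavelet-LBP (432).**  Single-level 3-D Haar DWT (8 sub-bands), each
  encoded by a rotation-invariant 3-D LBP — the count (0..26) of the 26
  Chebyshev-shell neighbours at radius r ∈ {1, 2, 3} that are ≥ the
  centre, edge-replicated at boundaries — followed by the 18 first-order
  statistics of the codes over the block-reduced region mask:
  8 × 3 × 18 = 432.  The count code is rotation-invariant by
  construction; a 2-D uniform-pattern code has no canonical 3-D
  analogue.  Haar is used so minimal regions remain decomposable.

The internal composition of the CoLIAGe and wavelet-LBP families has no
single standard decomposition; the ones above are configurable and their
totals (390/432) are contractual.

## Feature selection and modeling

The cascade, re-fit from scratch inside every training fold:

1. **Redundancy filter.**  Greedy scan in fixed column order; a column
   with |Spearman ρ| > 0.99 against an earlier kept column is dropped
   (the earlier column wins).  Constant columns are dropped with reason
   "constant".
2. **Univariate filter.**  Per feature: Shapiro–Wilk per class and
   Levene across classes gate the routing; when normality and variance
   homogeneity are *not* rejected (all p ≥ .05) a two-sample t-test is
   used, otherwise Mann–Whitney U.  Features with p < .05 are kept and
   the test actually used is recorded.  Classes with < 3 samples skip
   the gate (Mann–Whitney, logged).  A `gate="literal"` switch inverts
   the routing for sensitivity analyses, because the opposite reading of
   the gating convention is defensible from the method's description.
3. **Model-based selector** (one of three): SVM-RFE with the count
   chosen by internal 3-fold CV; random-forest importance above the mean
   importance; LASSO nonzero coefficients at the CV-chosen penalty.
   Empty selections fall back to the top-1 ranked feature, logged.

Classifiers: SVM (RBF), random forest, gradient boosting, logistic
regression, AdaBoost, bagging — 3 selectors × 6 classifiers = 18
pipelines, fixed sensible defaults, no nested tuning beyond the LASSO
penalty and RFE count.  Evaluation: stratified 5-fold CV at the lesion
level with all habitat rows of a lesion co-assigned (asserted on every
split); missing values imputed by training-fold medians;
habitat-level predicted probabilities averaged per lesion; the decision
threshold maximizes F1 on the training lesions over a 0.00–1.00 grid in
0.01 steps (ties toward 0.5); AUC/accuracy/sensitivity/specificity
reported per fold and as mean ± SD.  Habitat-generation methods are
compared by two-sided paired t-tests over their 18 pipeline-mean test
AUCs (pairing by identical pipeline spec; all-zero differences report
p = 1, an exactly constant nonzero shift p = 0).

Seven model variants are supported: nonhabitat (whole lesion — the same
pipeline run with one whole-lesion region, no special-cased code path),
Otsu, conventional, adapted, and the three combinations
adapted+nonhabitat, otsu+nonhabitat, adapted+otsu+nonhabitat.
Combinations concatenate feature columns at the lesion level: the first
constituent's rows are kept and each other constituent contributes its
per-lesion vector (whole-lesion row, or mean over habitat rows)
broadcast onto them.  Row pairing versus score fusion is an open design
point; column concatenation is the default.

## Synthetic phantoms

The generator emits ellipsoidal dual-channel lesions partitioned into
contiguous subregions (concentric shells or nearest-seed blobs), each
drawing PET/CT intensities from a habitat signature plus spatially
correlated Gaussian noise (smoothed white noise; the smoothing sigma is
the signature's "roughness" and differentiates the local-entropy
channels).  The four default signatures occupy the corners of a
PET × CT grid — necrotic (cold/low-attenuation), fibrotic-stromal
(cold/dense), inflamed (hot/low-attenuation), hypermetabolic
(hot/dense) — at 6 noise-SDs separation per axis, with a roughness ramp
0.8→2.0 voxels.  The grid layout matters: collinear, equally spaced
signatures are a degenerate case for variance-ratio cluster-count
criteria (which then favour k = 2), and complementary PET/CT contrast
is also the physiologically sensible configuration.  The two classes
differ in their composition distributions; by default the
high-uptake signature occurs only in the tumor-like class.

Known limitations, hence what passing tests do and do not show: no
point-spread/partial-volume blur, no respiratory motion, no attenuation
artifacts, sharp subregion boundaries.  Voxels whose 9×9×9
neighbourhood straddles a subregion interface carry intrinsically mixed
texture; in heavily mixed compositions these interface voxels form a
feature-space continuum that can inflate the CH-chosen habitat count.
The canonical recovery conditions (`recovery_cohort_spec`: 20+20
lesions, one dominant signature plus a 15% minority blob, 6 σ
separation) keep interface voxels a minority; recovery results on these
phantoms demonstrate correctness of the pipeline, not expected
performance on clinical images.

A companion generator (`make_feature_cohort`) emits habitat-level
feature rows directly (informative columns shifted by a chosen effect
size, within-lesion correlation via a shared lesion offset) for
exercising the selection/modeling stack at scale.

## Numerical conventions and problem sizes

* All randomness flows from explicit seeds; k-means uses 10 restarts;
  the full grid is reproducible bit-for-bit given one master seed.
* Entropy uses log₂ (bits); 0·log 0 = 0 throughout.
* Permutation-null checks of the modeling stack use 20 lesions per
  class and average over 10 independent permutations (each with a fresh
  cohort): a *single* global label permutation retains chance alignment
  with the latent feature structure of order 1/(2√n_lesions), which
  feature selection then exploits, so individual permutation AUCs
  scatter widely (roughly 0.3–0.75 at this size) even though their mean
  sits at chance.  Conclusions are therefore drawn only from the mean
  over permutations.
* Planted-k and ARI recovery studies use 20 lesions per class over 10
  seeds (k selection) and 5 paired seeds at separation levels 1/2/6 σ
  (ARI).  The levels probe the rising part of the recovery curve:
  above ~4 σ recovery saturates near ARI 1, where a monotonicity check
  would only measure noise.  The feature-count checks use one moderate
  synthetic VOI (~10 mm radius).
* Pipeline intermediates are cached under the output directory keyed by
  a hash of the governing parameters.
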