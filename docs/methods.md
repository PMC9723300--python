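# Methods

## Behavioral model

The Center of Cancellation (CoC) of a cancellation sheet is computed as the
mean normalized horizontal position of the cancelled targets, centred by the
sheet's mean target position, clipped to [−1, +1]. The centring term makes a
complete performance score exactly 0 on any sheet and reproduces the standard
range and sign convention (left-sided omissions → positive). On symmetric
sheets this coincides with the uncentred mean of cancelled positions; we do
not attempt to reproduce any particular scoring software beyond that. Sheets
with zero cancellations have no defined score; the scorer raises by default
and accepts an explicit imputation value (conventionally +1) because silent
imputation would bias simulation studies.

The regression target is the mean CoC over the letter and bells tests (the
remaining score if one test is missing), with negative means clamped to 0
*after* averaging — in a purely right-hemisphere cohort negative values are
noise around zero — and then square-root transformed to reduce skew. All
model-fit metrics (MAE, R²) are reported on this transformed scale, because
it is the variable the regression predicts. The neglect classification
cutoff is mean CoC ≥ 0.082 (per-test cutoffs 0.083 / 0.081 are exported as
constants).

Interrater reliability of ordinal ratings uses linearly weighted Cohen's
kappa, w_ij = |i−j|/(L−1), κ = 1 − Σw·O / Σw·E, with the weighted relative
agreement 100·(1 − Σw·O) reported alongside.

## Imaging operations

Maps live on a common voxel grid; no registration or resampling is performed
(inputs are assumed spatially normalized upstream; the NIfTI affine is
carried through I/O untouched). Segmentation thresholds an intensity volume
and keeps connected components of at least `min_cluster_voxels` voxels —
100 for lesion-scale delineation, 10 for punctate WMH. Connectivity defaults
to the most inclusive 26-neighborhood and is configurable (6/18/26); the
original semi-automated workflow does not document its rule, and a human
rater selected clusters interactively, which we replace by the fully
automatic keep-all-passing-clusters rule plus an optional component-label
whitelist and an optional exclusion mask (e.g. ventricles) for
reproducibility without a rater. WMH maps are masked by the patient's lesion
map (`wmh AND NOT lesion`) so the two damage maps are disjoint, and
hemisphere maps are obtained by splitting at the midsagittal plane; synthetic
grids use even nx with x increasing left→right, so the plane falls between
voxel columns nx/2−1 and nx/2.

## Feature construction

Lesion voxels damaged in at least 5 patients are retained; WMH voxels need
only one occurrence, because ratings integrate the whole WMH pattern
including rarely affected deep foci and the voxel encoding should not be
handicapped against them. Features are the dichotomized damage status.
Fusion variants:

- **concat_scalar** — append min-max normalized scalar(s): CHS, Fazekas PV,
  DS, PV+DS (two columns), WMH volume, or age. The WMH-volume scalar is
  normalized like the ratings for a uniform feature scale under the RBF
  kernel (the choice is ours; only ratings and age are prescribed).
- **concat_map** — append the WMH voxel block; PCA is fitted per block and
  the component sets concatenated.
- **add_map** — voxel-wise addition of lesion and WMH maps on the union of
  voxels {lesioned ≥ 5×} ∪ {hyperintense ≥ 1×}. With lesion-masked WMH the
  sum is binary; under permuted pairings overlaps occur and all non-zeros
  are reset to one. Left/right variants apply the same union-mask rule to
  the corresponding unilateral WMH maps.

PCA is computed on centred (not variance-scaled — the columns are binary
indicators on a common scale) voxel blocks via SVD; the retained k is the
smallest with cumulative explained-variance ratio ≥ 0.94, and each retained
score column is min-max normalized to [0, 1] like the scalars. Loading signs
are fixed by making each component's largest-magnitude element positive
(ties → first index) for determinism across BLAS builds. By default the PCA
is fitted once on the full cohort before cross-validation (pooled mode);
a fold-safe mode (PCA refitted inside each outer
training fold, `make_fold_safe_builder`) is available, since full-cohort PCA
lets test-fold rows influence the basis.

## Regression and model averaging

Epsilon-SVR with RBF kernel, ε = 0.1, through libsvm (scikit-learn), which
is deterministic given data and (C, γ, ε). Nested CV: 10 outer folds; the
outer-training set enters a 5-fold inner CV where every (C, γ) in the grid
C = 2⁻⁵…2¹⁵, γ = 2⁻¹⁵…2⁵ (×2 steps) is scored by mean MAE over validation
folds; the minimizer — ties broken toward smaller C then smaller γ,
preferring smoother models deterministically — is refit on the full outer
training set and predicts the held-out fold. Folds are built by shuffling
and cutting into contiguous blocks whose sizes differ by ≤ 1. Each
repetition r draws its randomization from substream (CV, r, ·) of the
experiment seed, so fold assignments are identical across model versions
within a repetition; per-patient predictions are averaged over repetitions
and R² of the averaged predictions is the reported fit. A reduced 5×5 grid
(C = 2⁻³,2⁰,…,2⁹; γ = 2⁻⁹,2⁻⁶,…,2³) spanning the same log-range coarsely is
provided for desk-scale runs.

Degenerate constant training targets make the inner search meaningless; the
grid minimum is returned by the tie rule.

## Permutation test

Permutation k draws a uniform pairing permutation from substream (PERM, k):
patient i keeps their lesion, age and target but receives patient π(i)'s WMH
data (maps, ratings and volume alike). Features are rebuilt from the
permuted pairing and the repetition-averaged pipeline is rerun with the
*same* repetition substreams; the null distribution collects the averaged-
prediction R² per permutation. p = (1 + #{null ≥ true})/(n_perm + 1), one-
tailed — the add-one rule keeps p > 0 and is the standard conservative
Monte-Carlo estimator; the 95th-percentile decision rule is reported
alongside for fidelity to the quantile formulation.

Two modes:

- **full** — hyperparameter search and PCA are rerun per permutation.
- **fast** (default for desk-scale runs; explicitly approximate) — the PCA
  is refitted on the permuted features, but the per-fold (C, γ) chosen on
  the true pairing are reused, so a permutation costs one SVR fit per outer
  fold and repetition. The PCA refit uses an n×n Gram-matrix shortcut whose
  scores equal the fit/transform path up to per-column orientation flips
  x → 1−x, which leave all pairwise distances — and hence RBF-SVR fits —
  unchanged. Type-I error of the fast mode is verified by simulation (the
  rejection fraction at α = 0.05 over 20 null cohorts stays nominal).

## Synthetic cohort generator

The generator emulates the *structure* of an acute right-hemisphere stroke
cohort on a 40×48×40 grid of 2 mm voxels (an ellipsoidal brain mask with two
paramedian box ventricles — a deliberately download-free stand-in, not an
anatomical template):

- **Lesions**: one connected blob per patient — a randomly anisotropic
  ellipsoid clipped to the right-hemisphere brain, radius-rescaled toward a
  target volume drawn from lognormal(μ = 2.87, σ = 0.94) cm³ (mean ≈ 27.5,
  SD ≈ 33, matching the clinical scale), truncated at 80 cm³ to fit the
  desk-scale brain.
- **WMH**: periventricular rims (box-shell of thickness 0–3 voxels, monotone
  in a latent PV severity) plus deep punctate foci (count monotone in a
  latent DS severity, radius 1–2 balls), per hemisphere, masked by the
  lesion. Hemisphere-specific deviations (SD 0.7 latent units,
  `hemi_asym_sd`) make WMH only *roughly* bilateral; without them the left
  map is an almost perfect proxy of the right and laterality effects are
  undetectable in principle. Mean total volume ≈ 8 cm³.
- **Latents**: a shared burden z with loadings 0.85 (PV) and 0.55 (DS) —
  giving the weak PV–DS association seen clinically (rating-level Spearman
  ≈ 0.34) — and age = 58.2 + 13.7·(0.65·z + √(1−0.65²)·ε), yielding an
  age–WMH-volume Spearman ≈ 0.4–0.5 at n = 500.
- **Ratings**: CHS 0–9 as a decile rank of total WMH volume; PV/DS 0–3 as
  monotone binnings of their latents; each plus rounded-Gaussian rater noise
  (SD 0.7), clipped; Fazekas total recomputed as PV + DS.
- **Behavior**: latent severity b = 0.9·(fraction of a fixed right
  temporo-parietal critical region overlapped by the lesion) + β_wmh·
  (standardized right-hemisphere WMH volume) + N(0, 0.10); letter and bells
  CoC are b plus independent N(0, 0.05) noise, clipped to [−1, 1]. An
  optional sheet mode generates symmetric cancellation sheets with a
  severity-dependent leftward miss profile and scores them through the CoC
  scorer. β_wmh = 0.10 by default, chosen so that the added-map model gains
  on the order of 0.05 R² over the base model (per-cohort gains range
  ~0.04–0.18) while the effect remains recoverable by the full pipeline at
  desk-scale settings; all betas are configurable, and β_wmh = 0 gives a
  null generator for type-I studies.

All randomness flows through seeded, integer-indexed substreams
(`RandomStream`, numpy `SeedSequence` spawn keys): cohorts, fold
randomizations, and permutations are each addressable and bit-reproducible
across runs and platforms.

What the generator does *not* emulate: MRI physics and partial-volume
effects, registration/normalization error, anatomical lesion anatomy
(vascular territories), rater drift, or any left-hemisphere behavioral
effects. Passing tests therefore demonstrate that the pipeline recovers
effects of the assumed generative form at realistic scales — not clinical
performance on real images.

## Problem sizes and numerical choices

Simulation studies in the test suite use n = 100 cohorts, the reduced 5×5
grid, 2–3 repetitions and 99–199 permutations (10–20 cohort replicates per
property); the acceptance script uses n = 103, 3 repetitions and 199
permutations with the fast permutation mode. These are the package's desk-
scale defaults; the full 21×21 grid, 10 repetitions and 5,000 full-mode
permutations are supported through configuration and scale linearly.
Ties in the grid search, PCA sign fixing, and fold construction are resolved
deterministically as described above; CSV outputs use a fixed float format
so reruns are byte-identical.

## Known limitations

- Full-cohort PCA (the default, protocol-faithful mode) is not leakage-free;
  use the fold-safe builder when estimating real-world generalization.
- The fast permutation mode reuses true-pairing hyperparameters; its null is
  validated empirically but is an approximation to the full mode.
- The quantized periventricular rim (4 thickness levels) makes WMH volume
  distributions mildly clumpy; rating simulations inherit that granularity.
- The critical-region overlap is a single-region linear effect; real
  lesion-deficit structure is richer, so absolute R² levels here should not
  be read as clinical effect sizes.
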