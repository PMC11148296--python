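# Methods

habitex implements a malignant-subregion texture-analysis pipeline for
breast DCE-MRI and a synthetic phantom cohort that exercises it end to
end. This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Kinetic-curve subregion model

A DCE study is a pre-contrast ("plain") volume plus six post-contrast
phases at 60–360 s. Each VOI voxel is summarized by two enhancement
ratios:

- early: `ER_first = (SI_first − SI_plain) / SI_plain`
- late: `ER_last = (SI_last − SI_first) / SI_first`

Voxels with `ER_first > 0.5` are *enhancing*; among them `ER_last > 0.1`
is *persistent* (continued uptake), `ER_last < −0.1` is *washout*, and the
remainder is *plateau*. The malignant subregion is washout ∪ plateau.
All three comparisons are strict, so the boundary values 0.5 and ±0.1
fall to non-enhancing and plateau respectively. Voxels whose plain or
first-phase signal is at or below `1e-6 × max(plain)` are labeled
non-enhancing rather than dividing by a near-zero baseline; the count is
logged. Classification runs on the native acquisition grid (the ratios
are properties of acquired voxels); the resulting mask is resampled
alongside the image with nearest-neighbour interpolation.

## Preprocessing

Order: μ±3σ normalization → isotropic resampling → discretization, so the
gray-level bins refer to final voxel values (a config switch reverses the
first two). Choices:

- **μ±3σ normalization** — z-score over the whole volume, rescaled by
  s = 100, clipped to ±3s. On these units a bin width of 5 yields ≈ 60–120
  gray levels in practice.
- **Resampling** — B-spline for images, nearest-neighbour for masks, to
  1×1×1 mm; the output grid keeps the input origin and extends to cover
  the physical extent within one voxel, with nearest-neighbour
  extrapolation at the far edge. Spline boundary effects decay
  geometrically (pole ≈ 0.27 per voxel), so values are interpolation-exact
  only ~12 voxels inside the domain — irrelevant for lesions away from
  the volume edge.
- **Discretization** — fixed bin width: `bin(x) = floor((x − min)/W) + 1`
  with W = 5, computed within the malignant mask per image.

## Feature set

Three families (466 intensity features + 14 shape features = 476 per
study at the default two LoG scales), named
`<image>_<family>_<feature>` with image ∈ {original,
log_sigma_{2.0,4.0}_mm_3D, wavelet_{LLL…HHH}}:

- **First-order (18)** — moments, percentiles, energy, plus Entropy and
  Uniformity on the fixed-bin-width histogram. Kurtosis is Pearson
  (normal ≈ 3); a constant sample has Skewness 0 and Kurtosis 3 by
  convention.
- **GLCM (24)** — distance 1, the 13 unique 3D directions each counted
  with its negation (symmetric matrices), features averaged over
  directions. Entropy-valued features are in bits; the information
  measures Imc1/Imc2 use natural logs throughout so
  `Imc2 = √(1 − exp(−2(HXY2 − HXY)))` is bounded in [0, 1) by
  construction. A region with no co-occurring pairs degenerates to the
  1×1 matrix (Idm = 1, ClusterShade = 0, Imc2 = 0, Correlation = MCC = 1).
- **Shape (14)** — volume, area and sphericity from a marching-cubes mesh
  of the mask (the binary mask is lightly Gaussian-smoothed, σ = 0.8
  voxels, before meshing; raw binary surfaces carry staircase facets that
  inflate the area of a rasterized sphere by ~16%). Maximum diameters are
  measured over the corner vertices of boundary voxels, which stays exact
  for degenerate masks (a single voxel gives √3·spacing) and overshoots a
  smooth shape's diameter by at most one voxel diagonal. Axis lengths are
  4√λ from the PCA of voxel centers; a single voxel has Elongation =
  Flatness = 1 by convention. With array axes (z, y, x), the "Slice"
  diameter drops z, "Column" drops y (the coronal projection), "Row"
  drops x.
- **Filters** — LoG at σ ∈ {2, 4} mm: Gaussian smoothing at the physical
  scale followed by the exact zero-sum [1, −2, 1]/h² Laplacian stencil
  (a truncated Gaussian-derivative kernel leaks a nonzero response on
  constant and linear fields). Wavelets: single-level undecimated
  separable coiflet-1, filters normalized to unit DC gain so a constant
  volume maps to itself in LLL; subband letters follow (z, y, x);
  odd-length axes are edge-padded and cropped back.

## Group screening and selection

Per feature, Shapiro–Wilk at α = 0.05 on each cohort gates an
equal-variance two-sample t-test (both normal) versus a Mann–Whitney U
test; p-values are two-sided and *unadjusted* — the screen keeps raw
p < 0.05 and draws the Manhattan reference line at −log₁₀(0.05) ≈ 1.301.
A Benjamini–Hochberg option exists and is off by default. Because
texture features are strongly mutually correlated, the *count* of
significant features under a null cohort is heavily overdispersed
relative to Binomial(p=0.05); the per-feature type-I rate is calibrated,
the count is not a calibrated statistic.

Selection is two-stage. Pruning: while any surviving pair has
|Pearson r| > 0.75 (pairs ordered by descending |r|, ties lexicographic),
drop the member with the higher mean absolute correlation against all
current survivors; constant features are dropped first. Iterative
processing (rather than one pass over the initial matrix) plus
deterministic ordering makes the result reproducible and idempotent.
Then greedy mRMR (MID variant): first pick maximizes MI(feature; label);
each later pick maximizes MI(f; label) − mean MI(f; selected). MI is
estimated on equal-frequency bins (⌊√n⌋ capped at 10; variables with at
most that many distinct values are used as-is) with the Miller–Madow
bias adjustment −(K_xy − K_x − K_y + 1)/(2n) applied inside the mRMR
score: the raw plug-in bias grows with table dimension, so uncorrected
scores systematically over-penalize continuous–continuous redundancy
relative to continuous–binary relevance. The `mutual_information`
function itself defaults to the uncorrected plug-in estimate.

## Classifier and evaluation

RBF-kernel SVM, C = 1, kernel scale by the `scale` convention,
class-balanced weights (the emulated cohort is 81 vs 38), Platt
probability calibration so the Youden cutoff lives on a probability
scale. Features are z-scored with statistics fit on training data only.
AUC is the trapezoidal rank statistic (ties ½), identical to
Mann–Whitney U/(n₁n₀); its 95% CI is DeLong's asymptotic interval.
The operating cutoff maximizes J = sensitivity + specificity − 1 over
observed scores, J-ties resolving to the larger cutoff (higher
specificity). Cross-validation is stratified 10-fold from a seed.

By default, screening and selection happen once on the full cohort and
only the classifier is cross-validated. This mirrors the common
radiomics protocol and is *optimistic*: under a null cohort the
full-cohort-selection CV AUC centers near 0.75, not 0.5. The
permutation-band check below therefore compares like with like, and a
leakage-free mode (`select_in_folds=True`) re-runs pruning + mRMR inside
each training fold.

## Phantom cohort

Default grid 64×64 in-plane × 48 slices at 1×1×1.2 mm; baseline signal
500 with additive Gaussian noise σ = 5 (1% — at such SNR the Rician and
Gaussian distributions are indistinguishable, and no pharmacokinetic
model is needed because only the two enhancement ratios reach the
classifier). Per-voxel time–intensity curves are piecewise linear: rise
to peak at 60 s, then a fixed per-phase slope. Archetype defaults
(amplitude, slope/phase): washout (0.8, −0.09), plateau (0.7, 0),
persistent (0.6, +0.09), non-enhancing (0.3, 0); each satisfies its
defining ratio inequalities with margin ≥ 0.02, and per-voxel amplitude
jitter (±10%) stays inside those margins. Lesions are ellipsoids
(semi-axes 12×14×11 mm) whose subregion layout is a Gaussian random
field smoothed at 4 mm and quantile-thresholded to the requested
fractions (default 0.4/0.3/0.3 washout/plateau/persistent, the rest
non-enhancing; the published cohort gives no composition data, so these
defaults are arbitrary and only anchor the tests).

Between-subject variability, without which any label effect separates
perfectly: lognormal size jitter (common factor sd 0.12, per-axis sd
0.06), subregion-fraction jitter (sd 0.05, renormalized), and a
lognormal jitter (sd 0.25) on the intensity-texture correlation length.

The binary label acts through two mechanisms with configurable effect
sizes (they are settings, not claims about tumors): high-label studies
multiply the texture correlation length inside the malignant subregion
by 1.5 (longer-range correlation raises GLCM homogeneity-type features
on filtered images) and the lesion's x semi-axis by 1.1 (stretching the
coronal footprint measured by Maximum2DDiameterColumn). These defaults
were fixed by a power simulation: at one third of the emulated cohort
(27 high/13 low) the pipeline's mean CV AUC exceeded 0.65 in 10/10
replicate cohorts.

What the phantom does **not** emulate: motion and B1 artifacts, coil
profiles, Rician noise floors, inter-phase misregistration, irregular
lesion margins, peritumoral tissue, or any real biological coupling
between Ki-67 and texture. Passing the synthetic recovery tests shows
the pipeline's machinery is correct and calibrated on its own terms; it
says nothing about predictive value on real lesions.

## Problem sizes used by the test suite

Chosen to keep a desk-scale run: the permutation-band check runs one
null cohort at the full n = 119 with 30 label permutations; the power
check runs 20 replicate cohorts at n = 40 (27/13, preserving the 81:38
imbalance); oracle-equivalence suites use ≤ 8³ volumes. The acceptance
script runs the complete pipeline twice at n = 119 (label effects on and
off).

## Known limitations

- DeLong CIs are asymptotic; at very small n or AUC near 1 they clip at
  the [0, 1] boundary rather than switching to an exact method.
- The corner-vertex diameter definition overestimates smooth-shape
  diameters by up to one voxel diagonal (exact for voxelized geometry).
- MI-based selection is noisy below n ≈ 100 subjects regardless of
  binning; the pruning stage, not mRMR, carries most of the reduction.
- The screen's significant-feature count is not a calibrated statistic
  under correlation (see above); compare models, not counts.
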