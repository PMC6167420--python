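# Methods

This note documents the models, conventions and parameter choices behind
`hipporad`, the reasoning where a design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real MRI cohorts.

## ROI handling

Volumes and masks must share a grid; the pipeline performs no
registration or atlas reslicing. A subregion patch is the intensity grid
cropped to the tight (half-open, 0-based) bounding box of the mask's
foreground, with the mask carried alongside: every downstream statistic
is computed over foreground voxels only, never over the zero-filled
background. Masks with fewer than 27 foreground voxels are rejected —
a 3×3×3 neighbourhood is the smallest region on which 3-D co-occurrence
and run-length statistics are not degenerate, and texture analysis of
smaller parcels is unreliable in any case.

## Gray-level quantization

GLCM/GLRLM features require discretized intensities. We use **Ng = 64
equal-width bins** spanning the foreground min–max range, top bin closed
so the maximum maps to level Ng. 64 levels is a common radiomics default
balancing matrix sparsity (small ROIs) against gray-level resolution; it
is a config knob (`ExtractionConfig.ng`). Because binning is affine in
the intensity range, all texture features are invariant under positive
affine intensity transforms x → ax + b (a > 0) — a property the suite
asserts. Intensities are otherwise used as stored; no global rescaling is
applied before extraction.

## Feature definitions

Per (subregion, band) cell: 14 first-order, 22 GLCM, 11 GLRLM features,
in the fixed registry order exported by `hipporad.registry` (the order
defines feature-table columns bit-for-bit; names follow the grammar
`<subregion>__<band>__<family>__<feature>`).

First-order skewness/kurtosis are moment ratios with population variance;
**kurtosis is non-excess** (Gaussian → 3; `excess_kurtosis=True` flips the
convention). First-order entropy/uniformity use the Ng-bin histogram.

GLCM: distance-1 offsets in the **13 unique 3-D directions**
(26-connectivity modulo point symmetry), pairs accumulated symmetrically
and normalized per direction; features are Haralick-style definitions
(both homogeneity variants, both informational measures of correlation,
IDMN/IDN normalized by Ng, GLCM variance about the marginal mean),
evaluated per direction and **averaged over non-empty directions** —
the dominant convention in the radiomics signature literature; matrix
pooling is deliberately not the default. All entropy-type features use
log base 2 with 0·log 0 ≡ 0; a fixed base change only rescales them.

GLRLM: maximal same-level runs along the rasters of each of the 13
directions, broken by background voxels and patch boundaries; the 11
standard run-emphasis/non-uniformity features, averaged over directions.
The conservation identity Σ R(g,l)·l = n_foreground holds per direction
and is property-tested.

Degenerate inputs map to finite values: zero-variance patches give
skewness = kurtosis = 0 and GLCM correlation = 0 (0/0 forms), constant
patches quantize to level 1 with a logged warning. Shape/volume features
are out of scope: with atlas-derived masks they are identical across
subjects by construction.

## Wavelet sub-bands

Single-level separable DWT with the 8-tap Symlet-4 filter pair, one
low/high-pass choice per axis → 8 sub-bands in the fixed order LLL, LLH,
LHL, LHH, HLL, HLH, HHL, HHH, decimated by 2 per axis. **Boundary
handling is periodization**, giving exactly ⌈n/2⌉ coefficients per axis;
on even-length axes the filter bank is orthogonal, so reconstruction is
exact and sub-band energies sum to the input energy (both asserted to
1e−8 / 1e−6 relative). Odd-length axes introduce a one-sample periodic
seam; feature extraction is unaffected, but the energy identity is only
tested on even shapes. A decimated (rather than stationary/undecimated)
transform is implemented; the 8-band naming is consistent with either,
and this choice is the documented divergence risk of the module.

Background voxels are zeroed before filtering, which confines background
leakage to a filter-width halo; a 2×2×2 max-pooled mask (foreground iff
any of the 8 source voxels is foreground) marks usable sub-band
coefficients, and sub-band statistics use those only. Sub-band
quantization is re-derived per band from that band's own coefficient
range — wavelet coefficients are signed and band ranges are incomparable.

## Screening statistics

Features are residualized on [1, age, gender] by OLS **fit over all
subjects jointly** — per-group fitting would absorb the group differences
the screen is meant to find — and returned as residual + grand mean.
Constant covariates are dropped with a warning; residuals are orthogonal
to the fitted covariates by construction (asserted).

The omnibus test is the classical one-way fixed-effects ANOVA, Bonferroni
corrected at α/N with α = 0.01 and N = 1692 (the full feature family).
Identical-everywhere columns follow the F = 0, P = 1 convention. Post hoc
pairwise tests default to **Welch** (unequal variances) for consistency
with the Welch form of the classifier's ranking statistic; the pooled
variant is a config flag. Post hoc P values are reported for all
features, flags only where the omnibus is significant. Spearman
correlations use midrank ties and the t approximation, computed over
pooled AD+aMCI subjects by default (per-group subsets are an argument);
MMSE screens at P < 0.01, AVLT at P < 0.05. P values are floored at
1e−300 before the −log10 transform used for heat-map output. A base
feature counts as "significant in a subregion" if any of that subregion's
columns sharing the (band, family, feature) identity is flagged; the
multi-subregion summary counts base features significant in > 1
subregion.

## Classification

RBF C-SVC (libsvm via scikit-learn). Per outer leave-one-out fold, the
training side alone determines: min-max normalization parameters
(train-only; test rows may fall outside [0,1] and are not clipped;
constant training features map to 0), the Welch-t ranking (sample
variances, descending |T|, ties by feature index; zero-scale features
score 0 if means agree and +inf otherwise), the top-k selection
(k ≤ 200), and — via an inner leave-one-out loop that repeats
normalization and ranking per inner fold — the (C, γ) pair maximizing
inner accuracy, ties resolved to the smallest C then the smallest γ
(prefers smoother models, deterministic). The no-leakage property is
enforced by construction and verified by a permutation-null test whose
mean accuracy must sit inside the 95% binomial chance band.

The default grid is the canonical powers-of-two search C ∈ 2⁻⁵…2¹⁵,
γ ∈ 2⁻¹⁵…2³ (step 2²); a 2×2 quick grid (`SMALL_GRID`) is used in
simulation studies and tests where grid breadth is not the question. The
feature count k is tuned **outside** the outer loop
(`select_feature_count` returns the accuracy-maximizing k, ties to
smaller k), which matches the usual reporting of a best-k accuracy but
carries an optimistic selection bias; per-k results are returned so the
bias is visible, and fully nested tuning is possible by treating k as
part of the inner search. Metrics: ACC/SEN/SPE with the patient group as
positive class, AUC by the Mann–Whitney rank formulation with midrank
ties. "Hyperplane distance" is the SVM decision value, oriented
patient-positive, correlated with MMSE by Pearson (the relationship of
interest is linear in the decision value); its sign is therefore negative
against MMSE, and magnitude is the meaningful quantity. Repeated
leave-4-out validation draws class-stratified (round-robin) holdouts so
small cohorts cannot lose a class, and is seed-reproducible.

The inner grid search fits the same tiny SVM thousands of times; it
calls scikit-learn's low-level libsvm binding directly to avoid
estimator-wrapper overhead (identical fits; the public `SVC` API is used
for every model whose outputs are reported).

## Synthetic cohorts

`hipporad.synthetic` generates the statistical structure the analysis
assumes, not anatomy. Per subject and subregion, an ellipsoidal ROI
(default semi-axes 7×5×4 voxels ≈ 600 voxels, hippocampal-subregion
scale; masks fixed across subjects) is filled with a smoothed Gaussian
random field. The texture knob is the smoothing sigma (correlation
length, voxels): longer correlation → smoother texture → lower GLCM
contrast/entropy, mimicking disease-related loss of fine gray-level
heterogeneity without claiming biological fidelity. Defaults: sigma
NC 1.0 / aMCI 1.3 / AD 1.6; base intensity 100, ROI sd 10 (arbitrary
units); additive group mean shifts 0 / −3 / −6. Each ROI's marginal
moments are rescaled exactly to its subject-level targets, and those
targets carry between-subject variability (mean jitter sd 2, sd jitter
lognormal σ 0.1) — without it, location/scale features would be constant
across subjects and group tests would run on rounding noise.

Covariates: group sizes default to 45/33/38 (NC/aMCI/AD); age is drawn
per group with overlapping distributions (means 68.2/70.6/71.7, sd
6.9/8.2/8.3) and gender is balanced, so the adjustment step has realistic
nuisance structure without confounding. Cognition derives from a latent
severity (0/1/2 + N(0, 0.3)): MMSE = 28.6 − 5.5·severity + N(0, 1.5)
clipped to [0, 30], and the four AVLT subscores are analogous noisy
monotone transforms — severity ordering NC > aMCI > AD in expectation is
asserted. `null_cohort` zeroes all group effects (exchangeable groups,
for type-I-error and permutation calibration); `separable_cohort` uses
extreme effects (sigma 0.5/1.5/2.5, shifts 0/−12/−25) so AD vs NC is
linearly separable in a handful of features.

What passing tests show: the feature kernels match brute-force oracles;
the screen is calibrated under the generator's null; the nested CV leaks
nothing and recovers planted effects monotonically. What they do not
show: robustness to scanner noise, partial-volume effects, registration
error, anatomical shape variation, or site effects — none of which the
generator emulates.

## Problem sizes in the test and acceptance runs

Simulation-based checks run at deliberately scaled-down sizes chosen as
the package's own operating points: oracle equivalence on ≤ 4×3×3 patches
over 100 seeds; screening calibration on 50 replicates of 36-subject ×
1692-feature null tables plus one image-based null cohort (5/group,
semi-axes 4×3×3); the permutation-null CV at n = 40 with 50 features,
k = 10 and the 2×2 grid over 20 permutations; effect-monotonicity at 25
replicates per effect level. The acceptance script uses a 15/12/15
cohort at default ROI size. Feature extraction runs at ≈ 0.6–1.2 s per
subject on one CPU.

## Known limitations

- Supplementary per-feature formula sheets vary across radiomics papers;
  where variants exist (homogeneity1 vs homogeneity2 denominators, sum
  variance about the sum average, GLCM variance about the marginal mean)
  the registry documents the convention implemented rather than guessing
  another implementation's intent.
- Leave-one-out error estimates are high-variance; the repeated
  leave-4-out mode exists precisely to expose that variance.
- The decimated wavelet transform is not shift-invariant; features from
  detail bands can change under single-voxel ROI translations.
- Min-max normalization uses train-only statistics (the defensible
  choice); whole-sample normalization would leak test-range information.
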