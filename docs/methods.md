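# Methods

## The analysis chain

The pipeline estimates group differences in morphometric similarity (MS)
and their transcriptomic correlates in five stages.

**MSN construction.** Each subject's seven regional features are z-scaled
across regions *per subject and per feature* (the features span four
orders of magnitude in physical units; without standardisation the
correlation would be dominated by the largest-scale feature). The MSN is
the correlation matrix of the standardized 7-vectors; the diagonal is
stored as zero and excluded from strength sums — a constant diagonal
would shift every region's strength equally and cancel in any group
contrast. Strength is the *signed* sum: negative regional MS is
meaningful (architectonic distinctiveness) and absolute sums would
destroy it. The Spearman variant ranks the seven features within each
region's vector with average ranks on ties. Whether z-scaling should be
per subject or pooled across the cohort is genuinely open; per-subject is
implemented because it makes each subject's MSN self-contained and
invariant to between-subject scale differences, and because the
between-group contrast is unchanged by any per-subject monotone affine
transform of features.

A structural fact worth knowing: after per-feature z-scaling across
regions, Σ_j cov(z_i, z_j) = 0 holds exactly for every region i, so
strengths are forced to straddle zero and are carried entirely by
*variance heterogeneity* between regions (the 1/s_j weights in the
correlation). This shapes both the synthetic generator and what planted
effects can do (below).

**Regional contrast.** One design matrix serves all regions:
intercept, group (user = 1), mean-centred age, sex (M = 1), age×sex
(centred age decorrelates the interaction from the main effects —
numerical conditioning only, the group contrast is unchanged), optionally
TIV, and for the CT model subject-mean cross-hemispheric CT. The
mass-univariate fit is a single normal-equations solve; statsmodels OLS
is the independent oracle in the test suite. Degenerate (perfect-fit)
regions get |t| capped at 1e6 with a warning rather than NaN. Welch's
correction is used for the global t-test since group variances are not
assumed equal. FDR families are kept separate by design: 308 regions,
7 network labels per atlas, 3 attendance flag sets. The network-level
test aggregates each subject's strength over a label's regions *then*
fits the same linear model — the simplest composition consistent with
reporting a per-network t and FDR p.

**Spin testing.** Rotations are drawn uniformly on SO(3)
(`scipy.stats.special_ortho_group`); the right hemisphere uses the
x-mirrored rotation so hemispheres spin as mirror images and no region
crosses hemispheres. Rotated parcels are reassigned to original parcel
slots as a bijection; collisions are resolved by minimum-total-distance
(Hungarian) matching by default, which in head-to-head calibration runs
had lower displacement distortion (0.122 vs 0.151 rad mean) and a null
rejection rate closer to nominal (0.060 vs 0.070 at α = 0.05 on smooth
map pairs) than greedy nearest-first resolution, and builds ensembles an
order of magnitude faster; greedy remains available
(`assignment="greedy"`). The p-value counts |null r| ≥ |observed r| with
+1 smoothing, so p ∈ [1/(n+1), 1]; two-sided by default because the
directional phrasing of "null exceeds observed" is ambiguous for negative
correlations, with `sidedness="greater"` provided. The test operates at
parcel-centroid level — the package consumes parcel tables, not surface
meshes — which is the same null family as vertex-level spinning at the
resolution the data actually have.

**PLS transcriptomics.** With a univariate response the first PLS
component is closed-form: w ∝ Xᵀ(y − ȳ). This is exact, fast and
oracle-checkable (the test suite checks it against an SVD of the
cross-covariance and against scikit-learn's iterative fit). Variance
explained is the squared correlation between regional scores Xw and y —
equivalently the R² of the rank-1 regression — chosen because it is the
only estimator of "variance of the response explained by one component"
that does not depend on how many further components one imagines.
Weights are oriented so the score–response correlation is non-negative;
flipping the response's sign flips weights and scores exactly and swaps
the positive/negative gene lists. Permutation of the response across
regions is the exchangeable null for the variance explained. The
bootstrap resamples regions with replacement, refits, sign-aligns each
bootstrap weight vector to the original, and forms Z = weight /
bootstrap SD; genes pass at the two-tailed 99% normal threshold and are
additionally screened by BH-FDR across genes, with each stage's
survivors reported separately so either convention can be read off.

**Caveat measured, not assumed:** the sign-aligned bootstrap Z is a
*ranking* statistic. Under a global null (no gene related to the
response) its spread is inflated (SD ≈ 1.45 rather than 1 at 152 regions
× 66 genes), so roughly 4–5% of null genes pass the nominal-1% threshold,
and when response and genes share smooth spatial structure, unplanted
genes with genuine incidental spatial correlation are also flagged. The
planted-gene recovery tests therefore assert rank-based recovery (median
planted-gene rank ≤ 10 of 66) rather than exact set identity.

**Pipeline.** Stage seeds derive from SHA-256 of `(master_seed,
stage_name)`, so adding a stage never perturbs earlier stages'
randomness; all outputs are TSV/JSON without timestamps and the manifest
records SHA-256 checksums, making fixed-seed reruns byte-identical. Map
outputs carry region_id keys to prevent silent misalignment between the
308-region and 152-region supports.

## The synthetic cohort generator

The generator's job is to produce data with the statistical structure the
analysis assumes, with known ground truth. Defaults are the study-scale
conditions: two groups of 24 subjects, 308 regions (152 left), 7
features, 66 genes.

**Regional profile.** All subjects are noisy copies of one shared
regions × 7 profile. Per feature it is a cytoarchitectonic class
signature (all regions of one von Economo class share a 7-feature
signature wherever they sit — the premise of MSN analysis) plus a
distance-local Gaussian field (exponential kernel on great-circle
distance, length scale 0.2 rad), coupled across features by a common
latent gradient (loading 0.6), and scaled by a smooth log-normal
amplitude ("gain") field with SD 0.7. The gain field is essential: given
the zero-sum constraint on strengths, only variance differences between
regions produce the wide, balanced strength distributions real MSNs show
(the generator produces per-subject strengths spanning roughly ±20 at
308 regions). Whole-cortex fields use a covariance that is a
positive-definite sum of a mirror-symmetric homotopic component (weight
0.5) and independent per-hemisphere components — each hemisphere lives on
its own sphere, and this is exactly the structure hemisphere-mirrored
spins preserve; a naive single kernel over both hemispheres' coordinates
would create unphysical cross-hemisphere coupling and an anti-conservative
spin test.

**Subject noise** is multiplicative in regional amplitude (SD 0.55 ×
gain): between-subject variability scales with how variable a region's
morphometry is, and — unlike additive noise — this preserves the
variance heterogeneity that carries MS strength at every noise level.
Features are emitted on physical scales (CT ≈ 2.5 ± 0.08 mm per z-unit,
etc.); the per-feature affine map is irrelevant to the MSN, which
re-standardises.

**Planted effects** act on covariance, not means — a mean shift would be
erased by the z-scaling and plant nothing. `effect_map[r]` is the signed
*direction* of the planted MS change, and the mechanism is chosen per
region so the change actually goes that way: independent
feature-decorrelating noise (SD = effect_scale × |effect| × gain) pulls a
region's MS toward zero, used when the requested direction opposes the
baseline-strength sign; shrinkage of the subject vector toward the shared
profile (factor exp(−effect_scale × |effect|)) homogenises the region and
amplifies its baseline MS, used when it matches. Because a planted change
is bounded by the region's baseline |strength|, the targeted effect-map
mode samples affected regions from the ~25 largest-|strength| regions and
signs effects toward zero — which also reproduces the empirical signature
of real case–control MSN studies, a strong negative spatial correlation
between the t-map and mean control MS (≈ −0.75 at the default operating
point). A uniform-random mode (no profile) exists for null and
exchangeability testing.

Spillover is intrinsic and quantified rather than wished away: removing a
region's correlations also removes its partners' shares of those same
edges, so flagged sets are a superset biased toward planted regions. The
operating point (effect_scale 2.5, noise 0.55, gain 0.7, length scale
0.2) was fixed by a pilot sweep before the recovery thresholds were
frozen, and validated on independent seed streams: sensitivity ≈ 0.84 at
FDR 0.05 with ≈ 3% of unaffected regions flagged, and exact null
calibration at effect_scale 0 (fraction of regional p < 0.05 equal to
0.05).

**Expression maps** are left-hemisphere only. Unplanted genes are
independent smooth fields (exponential kernel, length scale 0.5 rad,
z-scored per gene). A planted gene is a·(±normalised effect map) +
√(1−a²)·smooth noise, a = association strength, so a is the
construction-scale correlation with the effect map. Covariates: ages
N(55, 11) in both groups, balanced sex, ceremony attendance for users
lognormal(μ=5.91, σ=0.92) — matching a mean of ~563 and SD of ~650
attendances — and optional TIV correlated with summed parcel GM.

**What the generator does not emulate:** real morphometric feature
distributions (skewness, bounded supports), scanner/site effects,
spatially varying parcel sizes, subject motion artefacts, any specific
real effect topography, or the probe-level structure of real expression
atlases. Passing tests demonstrate that the *statistical machinery* is
calibrated and recovers effects of the planted covariance type at
realistic sample sizes — not that any particular real-data finding is
correct.

## Numerical choices and degenerate inputs

- Zero-variance features or constant region vectors raise errors naming
  the subject/feature/region; degeneracy thresholds are scale-aware
  (1e-12 relative), not exact-zero tests.
- BH-FDR delegates to statsmodels with significance recomputed as
  p_fdr < α (strict inequality).
- Bootstrap resamples with zero response variance are redrawn (logged).
- PLS with a response orthogonal to all genes returns zero weights and
  varexp 0 instead of dividing by zero.
- Spin ensembles validate that every permutation is a bijection;
  left-only ensembles index within the left-region ordering.
- The directionality summary returns NaN correlation for constant maps.

## Problem sizes

The test suite and acceptance script run at the study-scale defaults
(24+24 × 308 × 7; 66 genes × 152 regions) with 100 replicate cohorts for
regional recovery, 60 for gene recovery, 200 for null calibration, and
500 map pairs × 1,000 spins for autocorrelation robustness; resampling
depths of 500–1,000 are used for permutation/bootstrap stages, chosen as
the sizes at which the Monte-Carlo error of the assessed quantities is
comfortably below the margins being tested.

## Known limitations

- Rank-1 PLS only; no multi-component model selection.
- No mixed-effects or robust regression variants; no site harmonisation.
- Parcel-centroid spins cannot capture within-parcel geometry; parcels
  are treated as points of equal weight.
- The bootstrap gene Z is anti-conservative under the global null (see
  above); treat gene lists as rankings with a heuristic cutoff.
- The generator's effect mechanism can only move a region's MS between
  zero and an amplified multiple of its baseline; effects at
  near-zero-strength regions are unexpressible in the MS statistic — a
  property of the statistic itself, not of the implementation.
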