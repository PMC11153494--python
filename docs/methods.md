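# Methods

This note documents the models, algorithms and design choices behind
`taumap`, and what the synthetic-data experiments do and do not establish.

## Synthetic template and cohort

**Template geometry.** The template atlas is a parametric cortical ribbon,
not a brain-shaped mesh: a mid-surface `(x(u), y(v), z(u, v))` with gentle
sinusoidal curvature, thickened by a spatially varying half-thickness
`h(u, v) = h₀ + h_amp · sin(πu + φ₁) cos(πv + φ₂)` (defaults
h₀ = max(1.0 mm, 2.6 voxels), h_amp = 0.4 h₀). A voxel is foreground when
its center lies within `h + s/2` of the mid-surface (s = mean voxel
spacing), so the implied raster surface sits at the fg/bg voxel interface
exactly at offset h and the true thickness at any mid-surface point is the
analytic `2h(u, v)`. That analytic ground truth — the reason for choosing a
ribbon — is what the skeletonization and resampling stages are validated
against. Subregions are laid out as medial-to-lateral chart bands in the
order of standard MTL subregion maps, with TF/TH replacing the
entorhinal/perirhinal territory in the posterior third and the entorhinal
band subdivided into its eight cytoarchitectonic subfields (Eo/ER most
anterior, EC/ECL caudal). The default grid is 72×56×40 voxels at 0.4 mm
with a ~1400-vertex skeleton mesh; the minimum accepted grid (32, 24, 24)
is the smallest on which every subregion still receives voxels.

**Generative model.** Specimen burden is
`b(x) = severityᵢ · susceptibility(label(x)) · exp(−k·u(x)) · ε`,
with u the anterior→posterior fraction, k = 1.2 (about a 3× anterior-to-
posterior decline), and ε lognormal with σ = 0.3 normalized to unit mean.
Severity is `0.35 · exp(0.5·B + 0.03·(age − 75))`, increasing with Braak
B-score and age; ages are Normal(79, 10) clipped to 57–99 and B-scores are
drawn with probabilities (4, 17, 15, 11)/47, matching a realistic
AD-continuum autopsy cohort. Susceptibility ranks CA1 ≈ ERC > BA35 > S >
BA36 > TF/TH > PrS-PaS ≈ TE ≈ DG, with the anterior-lateral entorhinal
subfields highest and EC/ECL lowest; SRLM and the perforant pathway carry
zero burden (they contain no neurons) but *thin* with the burden of their
paired source region (CA1 and ERC respectively), mirroring the pairing rule
used in the analysis. Specimen thickness per skeleton vertex is
`T(v)·(1 − β·b(v)) + age_slope·(age − 75) + N(0, σ_t)` with β = 0.15 per
burden unit (a dimensionless fraction; generation is rejected if the
deterministic part would go non-positive), age_slope = −0.01 mm/yr and
σ_t = 0.25 mm, realized as a deformed binary segmentation by the same
interface-convention voxelization. Validity masks drop whole coronal slabs
(probability 0.15 per slab), emulating histology sections excluded for
misalignment; the same slabs invalidate the thickness field. Semi-
quantitative tau ratings discretize noisy site burden (ERC, DG, CA1) at the
fixed cuts 0.1/0.25/0.5/1.0 into {0, 0.5, 1, 2, 3} and average the three
sites; amyloid, TDP-43 and α-synuclein ratings are categorical draws with
realistic prevalence (TDP-43 and α-synuclein mostly zero) and, by default,
no effect on thickness. All randomness flows from one integer seed through
spawned per-specimen streams; identical seeds reproduce cohorts
bit-identically.

The ground-truth "affected region" recorded with each cohort is the set of
skeleton vertices whose cohort-mean expected thinning exceeds half its
maximum — the strongly affected territory a well-powered map should light
up.

**What the generator does not emulate.** Registration error fields,
hemisphere flipping, staining variation, spatially correlated thickness
noise, and realistic anatomy. Passing recovery tests therefore shows the
*statistical machinery* is correct and calibrated under the stated
generative assumptions, not that the pipeline is robust to registration or
segmentation failure modes of real specimens.

## Thickness estimation

The distance map is the exact Euclidean distance transform to the nearest
exterior voxel center (anisotropic spacing honored). The medial skeleton is
extracted by the feature-transform angle criterion: for each adjacent voxel
pair, the spokes from the pair midpoint to the two nearest-boundary points
are compared, and a point is medial when the angle exceeds
`prune_ratio·π` (default 0.72, i.e. ≈130°). Two refinements matter on
rasters: (i) only the more central voxel of a wide pair is marked, keeping
the sheet one voxel thin (marking both sides doubles the sheet and smears
it across layers); (ii) candidates closer than 1.6 voxels to the boundary
are discarded, because at such radii the quantized feature transform ties
arbitrarily between equidistant faces and manufactures wide angles along
edges and corners. The 130° threshold cleanly separates the genuine
mid-sheet (touch angle → 180°) from 90°-angle edge flanges even with
±30° quantization error at small radii. Radius = distance − s/2 (the
half-voxel offset between the boundary surface and the nearest exterior
voxel center); thickness = 2 × radius, exact on slab phantoms and within
half a voxel on voxel-centered spheres. Resampling onto the template
skeleton uses inverse-distance weights within max_distance = 2 voxel
spacings; vertices with no specimen point in range are missing, feeding the
25% validity rule downstream.

## Vertex-wise statistics

**Smoothing.** Explicit graph-heat iteration with uniform weights and step
0.25 (unconditionally stable for the normalized Laplacian), `ceil(T/0.25)`
steps, default T = 4. Missing data are handled by normalized convolution:
the value×validity and validity fields are diffused separately and their
ratio taken where the diffused validity exceeds 1e-6. Constants are exact
fixed points (with or without missingness) and each step is a convex
combination, so the discrete maximum principle holds. Smoothing precedes
the validity screen, which uses the pre-smoothing validity pattern.

**GLM.** Per-vertex OLS on valid rows; t = cᵀβ̂ / SE with df = n_valid − p.
A vertex is analyzed when at least `min_valid_fraction` (default 0.25) of
specimens are valid, the design has full column rank on the valid subset
(a constant variable of interest fails this) and df ≥ 1. Vertices are
grouped by identical validity patterns so each distinct pattern costs one
factorization; with slab-structured missingness the number of patterns is
small and the permutation loop is effectively vectorized.

**Clusters and FWE.** Per-vertex one-sided p-values use each vertex's own
df. Suprathreshold vertices (default uncorrected p < 0.01, negative
direction: pathology thins cortex) are grouped into maximal connected
components over mesh edges; the cluster statistic is vertex extent by
default, with summed |t| mass available. Freedman–Lane correction fits the
nuisance-only model, permutes its residuals by one global specimen
permutation per iteration, reconstructs pseudo-data, refits and re-extracts
clusters, and corrects each observed cluster against the permutation
distribution of the maximum statistic: Monte-Carlo p =
(1 + #{max ≥ observed}) / (1 + n_perm); exhaustive mode (n ≤ 8) enumerates
all n! permutations and reports the exact fraction.

**Missing data under permutation.** Each vertex keeps exactly its observed
valid rows, and the global permutation is *compressed* onto that subset:
the valid rows are reordered by their rank in the global permutation
(identical validity patterns share one coherent reordering; complete data
reduces to the plain global permutation). The alternative of dropping rows
missing in the permuted position was implemented and measured first: the
slab-structured df loss is spatially coherent, so permutation maps carry
systematically larger clusters than the observed map and the attained FWE
collapses toward zero as the mesh grows. The compression policy preserves
per-vertex degrees of freedom and restores calibration.

**Calibration and granularity.** On the calibration configuration (160
vertices, n = 20, 200 cohorts × 200 permutations) the attained FWE at
corrected α = 0.05 is ≈ 0.03–0.04, inside the 95% binomial band around the
nominal level. Because extent is an integer statistic, the attained size is
granular: on sparser meshes, where permutation max extents concentrate on
{1, 2}, the test becomes conservative (attained size near 0.01), never
anti-conservative. The mass statistic is continuous and avoids the
granularity when needed.

## ROI correlations

Partial Spearman correlation by rank residualization: all variables are
rank-transformed (average ranks for ties), x- and y-ranks are residualized
on the covariate ranks plus intercept, and the Pearson correlation of the
residuals is taken — equivalent to inverting the rank correlation matrix.
p-values use the t transform with df = n − 2 − k; zero covariates reduces
exactly to ordinary Spearman. Bootstrap intervals are percentile over case
resampling (degenerate constant resamples are redrawn and counted); the
reported interval is widened, if necessary, to bracket the point estimate.
The paired analysis runs each ROI against its burden-source ROI with
row-wise deletion per pair, reports ROIs with fewer than five complete
pairs as not computed, and includes the full-model OLS F-test p-value as
the joint age-and-burden significance summary. No multiple-comparison
correction is applied across ROIs by design.

One calibration subtlety: with the thinning effect disabled (β = 0) the
generator still couples burden and thickness through age (age raises
severity and independently thins cortex), so the zero-covariate correlation
is genuinely non-null. The null-calibration experiments therefore either
disable the age slope as well (exact null for the zero-covariate test) or
use the age-partial model; the ROI false-positive rate then sits within
binomial error of the nominal 0.05.

## Consensus labeling

Voxelwise plurality with ties broken toward the smallest label code; the
MRF mode maximizes vote-count log-likelihood (pseudo-count 0.01) plus
`β ×` (number of agreeing 6-neighbors) by synchronous ICM sweeps from the
majority-vote initialization (default β = 0.1, max 10 sweeps). β = 0 is
exactly plurality; increasing β only ever merges or removes label
components on the instances tested.

## Numerical and degenerate-input choices

Frequency thresholds use strict inequality (burden > τ). Welch
(unequal-variance) t is used for group comparisons. Average maps are
unweighted means over contributing specimens. Missing values are NaN plus
an explicit validity flag, never zero. Empty foregrounds, empty vote
lists, mismatched grids, all-masked ROIs vs absent ROIs, undersized Braak
groups, constant correlation inputs and rank-deficient nuisance models are
all rejected or flagged distinctly, as exercised in the tests. Problem
sizes in the test suite and acceptance script (48–1419-vertex skeletons,
cohorts of 15–40, 200–1000 permutations) were chosen so the full
validation runs in a few minutes on one CPU while keeping every statistical
check adequately powered.

## Known limitations

The skeletonization is raster-based; its half-voxel boundary convention is
exact for slab-like laminae but biases strongly curved structures by up to
half a voxel. The MRF fusion uses synchronous ICM, which finds a local
optimum only. Freedman–Lane with the compression policy is exact for
complete data and empirically calibrated under slab missingness, but no
finite-sample exactness claim is made under missingness. The generator's
thickness noise is spatially independent, which makes smoothing more
effective than it would be on real spatially correlated measurement error.
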