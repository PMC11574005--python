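# Methods

`shapestage` implements a subcortical shape-staging analysis as a tested,
reusable library, exercised end-to-end on a synthetic cohort generator that
emulates the statistical structure of a large multi-site Parkinson's disease
(PD) shape study. This note documents the models, the generator, the
numerical choices, and the limits of what the synthetic experiments can show.

## Synthetic atlas

Real pipelines extract registered triangulated surfaces of seven bilateral
subcortical structures (thalamus, caudate, putamen, globus pallidus,
hippocampus, amygdala, nucleus accumbens). Here each structure is a deformed
sphere: a uv-sphere (V = rings·cols + 2) scaled by per-structure half-axes
(rough mm scale), optionally tapered and bent (caudate and hippocampus get a
banana-like bend so medial curves are nontrivial), and given a seed-driven
random orientation. The undeformed unit-sphere directions are retained as
the per-vertex spherical registration used by the spin test. The default
configuration totals exactly 27,120 vertices across 14 structures, with
counts graded by realistic relative structure size (thalamus 2,702 per
hemisphere down to accumbens 1,202). The true per-structure counts and
template geometry of consortium atlases are not public; this atlas mirrors
the scale, not the anatomy. Vertex indices are 0-based and structure-blocked;
mesh adjacency never crosses structures. Meshes are exchanged as PLY (ascii
default; binary little-endian supported) through an internal reader that
validates headers strictly and reports the offending line.

Every generated mesh must pass a manifold check: no duplicate/degenerate
faces, every undirected edge shared by exactly two consistently wound faces,
and Euler characteristic V − E + F = 2.

## Medial-curve radial thickness

The shape feature is the distance from each surface vertex to a medial
curve — a smooth curve through the approximate center of the structure —
referred to as thickness, in mm:

1. first principal axis of the vertex cloud (SVD);
2. vertices sliced into `n_sections` equal-width bins along that axis
   (default 12; a bin with < 3 vertices raises a resolution error);
3. bin centroids, ordered along the axis;
4. a cubic smoothing spline through the centroids (`scipy.interpolate.splprep`,
   chord-length parameterization; `smoothing` is the spline residual budget,
   0 = interpolation).

Thickness is the minimum distance from a vertex to the curve, computed by
dense uniform sampling (default 513 parameter points, so doubling the
density keeps the old grid as a subset) followed by vectorized
golden-section refinement of the bracketing interval down to 1e−9. A curve
that degenerates to a single point falls back to distance-to-point with a
warning. The medial-curve discrepancy QC statistic is defined here as the
RMS distance between section centroids and the fitted curve, normalized by
mean thickness; it is 0 when the spline interpolates and grows with
smoothing — a package-specific operationalization, since no standard formula
for it is established.

These procedural choices (sectioning + spline, rather than a proprietary
skeletonization) make the feature fully testable: spheres give collinear
centroids, capped-cylinder phantoms give lateral thickness equal to the tube
radius within 1%, bent tubes track the analytic centerline, and thickness is
rigid-motion invariant to 1e−9 mm. No equivalence to any specific consortium
implementation is claimed.

## Synthetic cohorts

`simulate_cohort` draws per-group subject tables: controls (age
60.0 ± 12.2 y, 46% female) and PD patients (63.7 ± 9.8 y, 35% female) with
ICV ~ N(1.5e6, 1.5e5) mm³, assigned uniformly to `n_cohorts` acquisition
cohorts. PD subjects carry a modified Hoehn & Yahr stage
(1, 1.5, 2, 2.5, 3, 4, 5) and stage-graded clinical scores with a monotone
gradient — time since diagnosis increasing (2.5 → 12 y across stages), MoCA
decreasing (27 → 21.5), MDS-UPDRS3 increasing (18 → 47) — with configurable
missing-completely-at-random rates (default 20% for MoCA/UPDRS3) so
imputation paths are exercised. These anchors reproduce the published
demographics of large pooled PD samples at the summary level only.

`simulate_thickness` generates subjects × vertices values as

    thickness(v) = baseline(v) + β_age·age + β_sex·sex + β_icv·ICV
                   + u_cohort + δ_v(stage) + ε,

with baseline(v) the template mesh's own radial thickness, cohort random
intercepts u ~ N(0, 0.1²) mm, noise ε ~ N(0, 0.2²) mm, and δ_v a sum of
geodesic-Gaussian bumps (amplitude at the center vertex, σ = radius/2 in
edge hops). The default stage-effect plan mirrors the qualitative staging
pattern reported for PD — putamen incrementally thinner from HY1
(−0.10 → −0.40 mm), caudate and amygdala from HY2, hippocampus, accumbens
and thalamus from HY3, pallidum from HY4–5, plus early thalamic thickening
(+0.15 mm in HY1–2 at an off-center subregion) — with amplitudes on the
scale of published peak vertex effects (|b| ≈ 0.1–0.45 mm). Values are
clipped to > 0.01 mm (logged). The generator does not simulate scanner
effects beyond the cohort intercept, left/right symptom asymmetry, or any
MRI intensity/segmentation step; conclusions from passing tests are about
the statistical machinery, not about real-image robustness.

Stage bookkeeping follows the modified scale: 1.5 and 2.5 regroup to 2;
severe stages merge as HY45 (mass-univariate) or HY345 (classification).
Control matching is greedy nearest neighbor without replacement on
standardized age with exact sex matching (distance ∞ across sexes),
hard-to-match cases first, configurable ratio and caliper, seeded
tie-breaking. Propensity-score matching is deliberately not implemented;
only covariate distance.

## Vertex-wise mixed models and searchlight FDR

Each vertex's thickness is regressed on a predictor of interest (group
indicator or clinical score) with age, sex, ICV as nuisance covariates and
cohort as a random intercept, by REML. Because mass-univariate maps need
thousands of identical small fits, the primary solver profiles the REML
criterion down to a scalar optimization over the variance ratio
τ = σ_u²/σ_e² (closed-form GLS per candidate via per-group Woodbury
identities, bounded scalar minimization on log τ); a statsmodels `MixedLM`
backend is retained and agrees to ~1e−5 on coefficients in tests. When τ
hits the zero boundary, or only one cohort level is present, the fit is
exactly OLS. Inference is a two-sided Wald test with the normal reference
(not Satterthwaite); the type-I simulation in the acceptance suite
quantifies the consequence (rejection rate statistically indistinguishable
from α at n = 400, 5 cohorts). Thickness is analyzed in native mm by
default with an optional per-vertex z-scoring switch; rows with missing
predictor values are dropped per analysis.

Multiplicity is controlled with a searchlight FDR: Benjamini–Hochberg at
level q (default 0.05) applied within each vertex's geodesic neighborhood
(all vertices within `radius_hops` edge hops, default 5); a vertex is
significant iff its own p-value passes its neighborhood's BH threshold.
Radius ∞ reduces exactly to global BH (verified against statsmodels), and
radius 0 to the single-test rule p ≤ q. Simulations with 90% true nulls
show empirical FDR at or below q within Monte-Carlo error. Maps are
summarized per structure as (% significant vertices, signed peak beta among
significant vertices; 0 when none).

## Spin permutation test

Spatial similarity between two effect maps on one structure is the Pearson
correlation over vertices; its null preserves each map's spatial
autocorrelation by rotating one map on the registration sphere. Rotations
are Haar-uniform, built from unit quaternions (normalized 4-D Gaussian
draws); resampling is nearest spherical neighbor so the null map's value
set equals the data's (no interpolation). The two-sided p-value uses the
add-one permutation estimator p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + N);
its minimum is therefore 1/(N+1). Each of the 14 structures is tested on
its own spherical parameterization; no correction is applied across
structures. Unthresholded beta maps are the default input. Type-I error is
calibrated (rejection rate within the 99% binomial CI of α over 200
replicates of independent smoothed-noise pairs), and for smooth maps the
rotation null is demonstrably wider than the naive vertex-permutation null —
the property that motivates the test.

## Structured-sparsity classifiers

Binary (Logit-TVL1) and ordinal (Ordit) classifiers share one machinery: a
vertex weight map w penalized by λ₁‖w‖₁ (sparsity) plus λ_TV·TV(w), the
anisotropic graph total variation Σ_edges |w_i − w_j| over mesh adjacency
(spatial cohesion). The binary model is class-weighted logistic regression
with an unpenalized intercept; the ordinal model is a cumulative-logit
(proportional-odds) likelihood, P(stage ≤ k|x) = σ(θ_k − wᵀx), with a single
shared progression direction and K−1 thresholds parameterized as θ₁ plus
softplus increments, so strict ordering holds by construction. With K = 2
the ordinal objective coincides with the binary one under θ₁ = −intercept
(verified to 1e−6). An all-threshold loss was considered and rejected for
parsimony; the cumulative link keeps the "ordered, but no functional
stage–biomarker relationship" property at the link level.

Optimization is monotone FISTA with backtracking line search and restart on
momentum overshoot, so the recorded objective trace is non-increasing. The
composite prox of λ₁‖·‖₁ + λ_TV‖D·‖₁ is computed exactly by solving its
dual — a box-constrained least-squares over the stacked operators [I; D] —
with projected FISTA and a duality-gap stopping rule (gap tolerance 1e−7 in
the solver loop); strong convexity converts the gap into a sup-norm bound
‖x − x*‖∞ ≤ √(2·gap), and the prox matches an independent box-constrained
least-squares oracle to 1e−6 on all small random graphs tested.

Model selection is stratified (nested) cross-validated grid search over
(λ₁, λ_TV), 4 outer × 4 inner folds by default, ROC-AUC for binary tasks
and macro-averaged F1 ("balanced F1") for ordinal ones. Imputation
(training-column means) and inverse-frequency class weights
(n_total/(n_classes·n_c)) are fitted inside each training fold — no test
leakage, verified by a shifted-test-distribution check. The selection rule
is the one-standard-error rule: among grid points within one SE of the best
inner-CV score, take the largest total penalty. This is the standard
parsimony convention for regularization paths and matters here: CV cannot
distinguish a sparse focal model from a dense one within noise, and the
sparser model is the interpretable one. A `"best"` rule (maximum mean
score, ties to the larger penalty) is available. Learned maps are reported
in SD units of the weights (w/SD(w)).

## Pipeline

`run_pipeline` (CLI: `shapestage run`) chains the full analysis from one
YAML-able config: atlas → cohort + thickness simulation → per-HY-stage
case-control effect maps against age/sex-matched controls (HY1, HY2, HY3,
HY45) → spin similarity for consecutive stage-map pairs per structure →
nested-CV classification (PD vs control, HY1 vs HY2, HY2 vs HY345, and the
3-class ordinal task). Every random draw traces to a named child seed
derived from the master seed via CRC-32 + `SeedSequence`; numeric outputs
are written with a fixed "%.10g" float format, so re-running a config
reproduces every TSV/JSON byte for byte. Any stage failure aborts with the
failing stage named and a `FAILED` marker beside the partial outputs. The
bundled demonstration config uses the 14-structure layout at reduced mesh
resolution (50 vertices per structure, 700 total), 260 subjects, 150
rotations and a 2-point λ grid, and plants no effect in the pallidum as a
negative control; it runs in about two minutes on one CPU.

Problem sizes in the test and acceptance suites (642-vertex spheres for
spin calibration, 162-vertex spheres for FDR and support-recovery
simulations, n = 300–400 subjects, 100–1000 Monte-Carlo replicates, demo
pipeline at 700 atlas vertices) were chosen as the smallest scales at which
the statistical properties under test are identifiable; all are
configurable upward.

## Known limitations

- The medial-curve construction and the discrepancy statistic are this
  package's own documented procedures; numeric agreement with other shape
  pipelines is not expected.
- Wald-normal p-values slightly understate uncertainty in the variance
  components when cohorts are few; the calibration simulation bounds the
  effect at the sizes used.
- The searchlight FDR controls FDR empirically in the simulated designs;
  no finite-sample proof is claimed for dependent p-fields.
- Synthetic cohorts have Gaussian, spatially stationary noise within
  structures; real morphometric noise is neither. Classification metrics on
  synthetic data say nothing about achievable accuracy on real cohorts.
- The spin test assumes per-structure spherical registration; maps on
  non-registered meshes are out of scope.
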