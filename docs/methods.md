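# Methods

This note documents the models, conventions and numerical choices behind
`radtex`, in the spirit of the model documentation shipped by packages such
as statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic experiments do and do not show.

## Gray-level discretization

All texture matrices operate on an integer alphabet `1..Ng`. Intensities
inside the ROI are binned into a fixed *count* of equal-width bins (default
32) spanning the in-mask range; the maximum falls in the top (right-closed)
bin, so exactly `Ng` levels exist. A constant region collapses to `Ng = 1`.
Voxels outside the mask carry the sentinel level 0 and never enter any
pair, zone, run or neighborhood count. Fixed bin count (rather than fixed
bin width) keeps the matrix dimensions bounded and comparable across scans
whose intensity scales differ, which matters because MRI intensities have
no absolute units.

## Texture matrices

Conventions that are genuinely open in the literature, fixed here:

- **GLCM** is symmetric by default (each offset counted forward and
  backward); the asymmetric variant is retained as the building block for
  the DGLM. 3D aggregation uses the 13 unique nearest-neighbor directions
  at distance δ = 1, with *features averaged after per-direction
  computation*, not matrices summed. A 2D mode restricts to the 4 in-plane
  directions.
- **GLSZM** zones use maximal (26-) connectivity in 3D, 8-connectivity
  in-plane in 2D mode ("same level irrespective of direction" read as the
  most permissive adjacency).
- **NGTDM** neighborhood means exclude the center voxel and average only
  over in-mask neighbors (`v` = the actual neighbor count); voxels with no
  valid neighbor are excluded from `n_i` and `s_i` entirely. Including the
  center would make the difference sums systematically biased toward zero
  and is rejected.
- **GLDM** dependence counts start at column `d = 0` (an isolated voxel has
  zero dependent neighbors). Wherever a squared or reciprocal dependence
  term appears in a feature formula, `d` is mapped to `d + 1`, so the
  all-isolated matrix scores emphasis 1 rather than dividing by zero.
- Divide-by-zero guards: NGTDM coarseness returns the sentinel `1e6` for a
  perfectly flat texture; busyness/contrast/complexity/strength return 0
  when only one level is present; GLCM correlation returns 0 when a
  marginal is degenerate; skewness/kurtosis of constant distributions are 0.

Every builder is validated entry-for-entry against an exhaustive
brute-force enumerator (explicit loops over voxels and neighbors) on
hundreds of random masked volumes, and every feature formula against an
independent direct-summation implementation at 1e-10 relative tolerance.

## The decreasing gray-level matrix (DGLM)

The DGLM is a directional co-occurrence filter: for an in-plane offset
(angle ∈ {0°, 45°, 90°, 135°}, distance δ), ordered in-mask pixel pairs
`(x, x+offset)` with levels `(i, j)` are counted **only when i ≤ j**. The
result is exactly the asymmetric co-occurrence matrix masked to its upper
triangle (an identity asserted in tests), accumulated over axial slices and
*not* symmetrized. Features (energy, first-order mean of the row index and
its absolute deviation / skewness / kurtosis, entropy, autocorrelation,
information measure of correlation, maximal correlation coefficient) are
computed per angle and averaged over angles with nonempty matrices.

Two conventions required a decision:

- *Keep-condition*: the defining formula says `i ≤ j` while a figure-level
  description suggests `i < j`. The formula is taken as normative (diagonal
  pairs are kept); a `strict=True` flag flips to `i < j`.
- *"First-order mean"*: the moments are taken over the first index `i`
  weighted by the normalized matrix `p(i, j)` (the marginal-over-rows
  convention); on a constant image this makes the DGLM mean equal the
  single gray level exactly.

What the DGLM adds: every standard family is invariant under reversing the
order of a voxel pair (GLCM by symmetrization; GLRLM/GLSZM by unordered
runs/zones; NGTDM/GLDM through absolute differences). Textures that are
mirror images of each other — slow-rise/fast-fall versus fast-rise/slow-fall
intensity ramps — are therefore *indistinguishable* to the standard set, but
differ in how many pairs survive the `i ≤ j` filter and in the shape of the
surviving distribution. The ablation experiment below quantifies this.
A corollary limitation: DGLM features are chirality-sensitive, so flip
augmentation (which mirrors the texture) destroys exactly the signal DGLM
measures; augmentation plans for DGLM-driven models should prefer rotations
and shears.

## Shape features

The ROI surface is triangulated by marching cubes at isolevel 0.5 after
one-voxel zero padding (meshes are always closed). The binary indicator is
lightly Gaussian-smoothed (σ = 0.5 voxels) before isosurfacing: a raw
binary staircase surface overestimates the area of a digitized ball by ~9%,
while σ = 0.5 brings the ball (r = 15) to within ~4% in area and ~0.4% in
volume, and a 10³ cube to within ~3% in volume. For ROIs so small that
smoothing erases the isolevel crossing, the raw mask is used; a single
voxel then meshes to the octahedron through its face midpoints (volume
1/6) — coarse, but closed and well defined. Mesh volume is the absolute sum
of signed tetrahedron volumes `O_x · (O_y × O_z)/6` over faces; area the
sum of half cross-product magnitudes. Diameters are maximal pairwise vertex
distances (convex-hull-reduced), in 3D and in axial projection. Axis
lengths use the population covariance of in-mask voxel physical
coordinates: length `4√γ`, elongation `√(γ_minor/γ_major)`, flatness
`√(γ_least/γ_major)` — the square-root convention, consistent with the
`4√γ` axis definition. Degenerate (coplanar) masks report flatness 0 with a
warning.

## First-order features

Sixteen statistics of the raw in-mask intensities with population (1/N)
moments; kurtosis is not excess-corrected (normal ≈ 3). Energy uses voxel
shift constant `c = 0`; entropy alone is computed on the discretized
histogram in bits with a machine-epsilon guard inside the logarithm;
percentiles interpolate linearly between order statistics.

## Augmentation

The four affine families (horizontal/vertical flips, scaling, rotation,
shear) act in-plane, slice-wise, about the slice center, because their
defining matrices are 2×2. Intensities are resampled linearly, masks by
nearest neighbor (masks stay binary); out-of-bounds is zero-filled; flips
are exact axis reversals. Randomized parameters draw uniformly from the
standard ranges (angle 25–195°, shear 0.3–0.7, scale 0.8–1.2) under an
explicit seed. Resampling matrices are rounded at 1e-12 so exact 90°/180°
rotations stay on-grid. Every augmented copy inherits its parent's
`source_id`, which the evaluation layer uses for grouping.

## Classification and evaluation

The learners are stock implementations (scikit-learn bagging / random
forest / AdaBoost / gradient boosting, plus XGBoost); the package's
contribution is the protocol around them. Cross-validation is stratified by
label and *grouped by source scan* (`StratifiedGroupKFold`), so augmented
copies can never leak across folds — the splitter asserts this on every
fold. Rows are canonically re-ordered internally (by source id, then
feature values), making evaluation exactly invariant to table row
shuffling. Confusion counts are pooled over folds; AUC is the Mann–Whitney
rank statistic (midranks for ties) on pooled out-of-fold scores,
cross-checked against `roc_auc_score` in tests. Feature selection uses
normalized impurity importances with alphabetical tie-breaking; no
hyperparameter search is performed (defaults: 100–200 trees per ensemble).

On the synthetic benchmarks here, boosting and bagging ensembles perform
comparably (mean AUC within ~0.05 of each other over seeds); reported
orderings of ensemble families on clinical cohorts are cohort properties,
not properties of the algorithms, and the test suite asserts only
competitiveness.

## Synthetic phantoms: what they emulate, and what not

`generate_phantom` produces Gaussian random fields: white noise convolved
with a Gaussian kernel of class-specific correlation length λ (voxels),
rescaled to unit marginal sd, times σ_n, plus a class mean offset Δμ inside
an ellipsoidal ROI. Defaults define the study conditions used throughout
tests and the acceptance script:

| parameter | default | meaning |
| --- | --- | --- |
| grid | 32³ voxels, unit spacing | phantom volume |
| ROI | ellipsoid semi-axes (12, 12, 10) | nontrivial shape + boundary handling |
| λ₀ / λ₁ | 0 / 4 voxels | class correlation lengths ("large effect") |
| σ_n | 1 | marginal noise sd |
| Δμ | 1 σ_n | class-1 mean offset inside ROI |
| effect_size | 1 | scales (λ₁ − λ₀) and Δμ jointly; 0 ⇒ exchangeable classes |

Correlation length is the right dial because it is precisely what
co-occurrence/dependence statistics measure, making recovery interpretable.
The phantoms deliberately do **not** model anatomy, bias fields, partial
volume, scanner heterogeneity or registration error, so a perfect synthetic
AUC demonstrates pipeline correctness (features measure what they claim,
no leakage), not clinical performance.

`generate_anisotropic_dataset` produces the DGLM ablation benchmark:
sawtooth ramps along one axis (period 8 voxels, rise fraction 0.8 vs 0.2,
amplitude 1, noise sd 0.25, random phase), i.e., the two classes are
spatial mirror images with identical symmetric-pair statistics. Standard
features score chance-level AUC on it; adding DGLM features raises mean
grouped-CV AUC by ≈ 0.2–0.3 with a strict improvement in essentially every
seed (recomputed by `scripts/acceptance.py`).

## Problem sizes and experiment design

Simulation-based checks use: recovery at 50 phantoms/class on 32³ grids
(5-fold grouped gradient boosting); null calibration at effect 0 with 12
scans/class on 28³ grids, flip-augmented ×3, pooled over 10 seeds and
compared against a 3·(0.5/√N) binomial band around 0.5; DGLM ablation at 20
scans/class on 32×32×8 grids over 10 seeds. These sizes give stable
statistics on a single CPU while keeping each experiment's sampling noise
well inside the asserted margins.

## Known limitations

- DGLM is defined in 2D (axial slices, 4 angles); a 13-direction 3D
  generalization is a documented extension, not default behavior.
- Matrices are accumulated per angle over all slices, then featurized
  (pool-then-featurize); per-slice featurization would weight thin slices
  differently.
- Maximal-correlation-coefficient eigenvalues of degenerate (single-level)
  matrices are defined as 1 by convention.
- Preprocessing that precedes feature extraction in a clinical workflow
  (de-obliquing, inhomogeneity correction, skull stripping, registration)
  is out of scope; inputs are assumed spatially normalized with a valid
  brain mask.
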