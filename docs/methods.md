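# Methods

This note documents the models, rules and numerical choices behind
`valvemorph`, and what the synthetic-data generator does and does not
emulate.

## Mesh volumetrics

A valve is an indexed triangle surface in mm, pre-aligned so that x is the
anterior–posterior axis, y the dorso-ventral axis, and z the
commissure-normal direction (the commissural plane is z = 0). Alignment to
the hinge axis is an *input contract*: meshes must arrive aligned, because
the alignment procedure belongs to the scan-processing stage, not to this
package. All volumes use the signed-tetrahedra sum
`V = (1/6) Σ_t v0 · (v1 × v2)`, exact for closed, consistently
outward-wound surfaces and origin-dependent for open ones.

**Internal volume of the open interior surface.** The shell interior is an
open surface with one boundary loop in the commissural plane, and its
enclosed volume depends on how the opening is closed. Two modes are
provided:

- `capped` (default) — the boundary loop is triangulated with a fan to the
  loop's own centroid and the closed mesh's volume taken. This is the
  geometrically interpretable choice: the cavity bounded by the interior
  surface and the commissural plane.
- `origin_fan` — the surface is translated so its area-weighted centroid is
  at the origin and the raw signed-tetrahedra sum taken, which implicitly
  fans the opening to that centroid. On a unit hemisphere the two differ by
  exactly the cone from the surface centroid (at z = r/2) to the boundary
  circle: 2π/3 vs π/2 per unit r³.

The area-weighted surface centroid is used (rather than the plain vertex
centroid) because the two agree only for uniform meshing; the mode used is
recorded in the output metadata. Both volumes are reported when they differ
by more than 1%.

**Numerical choices.** Vertex welding on load uses a tolerance of 1e-6 of
the bounding-box diagonal (scale-free); triangles below 1e-12 mm² are
dropped; validity booleans (closed, 2-manifold, winding-consistent,
boundary-loop count) are exact properties of the face-edge incidence
structure and nothing is silently repaired — a shell solid that fails
closed+manifold is refused with the report attached. Covariance inverse
square roots (below) floor eigenvalues at 1e-10 of the largest, since
near-ultrametric trees give ill-conditioned matrices.

## Morphometric variables

`pSV = TSV/(TSV + TIV)` with TSV and TIV twice the single-valve shell and
internal volumes (the studied taxa are equivalve). `SL` is the x extent of
the bounding box, `height` the y extent, `width` twice the z extent (a
single valve spans only half the animal's width), and `XS = width/height`.
`logSL` defaults to log10 (configurable to natural log); the base is a
reporting convention and affects no ratio statistic. pSV and XS are
invariant under uniform scaling and under mirroring a right valve to a
left valve (reflection across z = 0 with winding flip); SL scales
linearly. These invariances are enforced by tests at 1e-9 relative
tolerance.

## Functional-group classification

Six substratum-use categories. Precedence: an explicit borer / nestler /
epifaunal annotation wins (those modes are defined by the substrate
occupied, not burial depth); asiphonate infauna are `infaunal_asiphonate`;
siphonate species with SL < 50 mm are assumed shallow-burrowing; otherwise
the estimated siphon length, sinus-depth fraction × SL, classifies the
specimen as deep if it exceeds 30 mm. Both cutoffs are read strictly:
SL = 50 mm goes to the sinus check, an estimate of exactly 30 mm is
shallow. The general rule (fraction × SL vs 30 mm) is implemented rather
than any worked single-case arithmetic. A siphonate specimen at or above
50 mm with no sinus measurement is an error, not a silent default, and a
manual override (the annotation column) exists for taxa classified from
direct observation.

## Disparity rarefaction

For each group and variable, subsamples of size n (default grid 5 … group
size) are drawn *without replacement* (1000 replicates by default); the
statistic is the sample variance (n−1 denominator) or the cumulative range.
Sampling without replacement is the substantive choice: it makes every
replicate at n = N equal the full-sample statistic, so the curve pins to
the measured full-sample point. The 95% envelope is the 2.5/97.5 percentile
interval of the replicates. Two thresholds are derived:

- **divergence** — the smallest shared n at which two groups' envelopes are
  disjoint *and remain disjoint at every larger shared n*; persistence
  guards against sporadic Monte-Carlo crossings.
- **range stabilization** — the smallest n whose median range is within a
  tolerance (default 1%, exposed as a flag) of the full-sample range,
  persistently.

The without-replacement sample variance is unbiased for the group variance
at every n, and the per-n mean is stored alongside the median so the
property is testable.

## Phylogenetic comparative statistics

The Brownian-motion covariance of tips i, j is the depth of their most
recent common ancestor from the root; the diagonal holds root-to-tip
distances. Pagel's λ multiplies the off-diagonals (λ = 0 star phylogeny,
λ = 1 full Brownian structure).

**Blomberg's K** is the ratio of the observed MSE of tip values around the
GLS (phylogenetic) mean to the C-standardized MSE, scaled by its
Brownian-motion expectation `(tr C − n/(1'C⁻¹1))/(n − 1)` so K = 1 under
BM on the given tree. The permutation test shuffles values across tips;
p = (count + 1)/(n_perm + 1).

**Pagel's λ** maximizes the profile multivariate-normal log-likelihood
(mean and σ² profiled out analytically) over [0, λ_max], where λ_max is the
largest λ keeping the transformed matrix positive definite (found by
bisection on a Cholesky test, capped at 2). The p-value is a
likelihood-ratio test against λ = 0 (χ², 1 df); a permutation mechanism is
available through the same tip-shuffling route as K.

**GLS linear models with RRPP.** The response and design are premultiplied
by C^(−1/2) (eigendecomposition with the eigenvalue floor above). Sums of
squares are sequential (type I) in the declared term order — matching the
convention of ANOVA tables with ordered terms and single-df covariates —
with F = MS_term / MS_residual from the full model. Inference is by
residual randomization: for each term, the residuals of the reduced model
containing all preceding terms are permuted, added back to the reduced
fitted values, and the term's F recomputed; the observed arrangement counts
as one permutation, so p ∈ [1/(n_perm+1), 1]. The effect size Z is the
standard deviate of log F within the permutation distribution (computed on
log F; negative Z simply means the observed F sits below the permutation
mean). A term that adds no estimable dimension raises an aliased-term
error naming the term; a saturated fit reports an infinite F rather than
failing. With the identity covariance and many permutations the p-values
converge to classical parametric ANOVA p-values on balanced normal data,
and the bookkeeping identities (ΣDf, ΣSS, ΣRsq) hold on every fitted
table by construction and by test.

## Synthetic data

**Parametric valves.** A valve is the shell of material between nested
hemi-ellipsoids (z ≥ 0), closed by a flat annulus in the commissural
plane; the interior surface is the open inner hemi-ellipsoid. Hemisphere
meshing uses 4·2^s latitude rings (s = subdivision, default 4) and twice
as many longitude segments. All analytic quantities are closed form:
hemi-ellipsoid volume (2/3)πabc, hence pSV = (abc − a′b′c′)/abc. Because
inner and outer surfaces are linear images of the same discretized unit
hemisphere, the discretization factor cancels in pSV exactly — the
measured ratio is correct to machine precision at any resolution, while
absolute volumes converge quadratically with subdivision. The proxy
deliberately omits coiling, ornament, hinge teeth and pallial-sinus
geometry: none of those enter any implemented formula, which also means
passing tests say nothing about meshes whose openings are not planar
single loops.

**Birth–death trees.** Gillespie simulation from one lineage; when the
n-th extant lineage appears the clock runs on to just before the next
event (guaranteeing positive terminal branches and exactly n tips),
extinct side branches are pruned and the tree starts at the root split.
Runs where the clade dies out are retried. Under pure birth the expected
crown age is (H_n − 1)/b, which the simulator reproduces and the tests
check.

**Brownian traits.** Independent normal increments per branch with
variance σ²·length, accumulated root to tip; tip covariance is σ²C by
construction.

**Cohorts.** The default cohort mirrors the study system's structure:
family sample sizes 12 (Astartidae), 72 (Carditidae), 40 (Crassatellidae),
126 (Veneridae) on a fixed two-clade backbone
((Astartidae, (Carditidae, Crassatellidae)), Veneridae) with simulated
crown groups, root at 200 Myr. Family trait parameters encode the reported
contrasts: archiheterodont pSV means 0.30–0.40 vs venerid 0.15 (pSV is
simulated on the logit scale to respect the (0, 1) bounds, sd 0.30–0.35
vs 0.60 for venerids, giving venerids the broader pSV spread); venerid
logSL mean 1.6 (≈ 40 mm) with the smallest sd (0.15) against
archiheterodont sds of 0.25–0.35; XS near 1 everywhere with carditids most
variable (sd 0.15). A few carditids are epifaunal and a few venerids are
borers/nestlers, so all six substratum groups are realised through the
actual classification rules (sinus fractions drawn uniform on 0.1–0.8) —
categories are never assigned directly. In the default
brownian-with-family-shifts mode each trait is Brownian motion on the full
tree, standardized within family and rescaled to the family mean and sd (a
linear map, so phylogenetic signal is preserved); an independent-draws
mode provides the no-signal contrast. Every generator is a deterministic
function of its seed, and emitted meshes invert the drawn (pSV, SL, XS)
through the analytic formulas so re-measuring them recovers the drawn
values to 1%.

What the cohort does **not** emulate: real venerid/archiheterodont
morphospace shape beyond first and second moments, measurement error,
fossil sampling, intraspecific variation, or any correlation structure
between the three variables other than what shared phylogeny induces.
Passing tests therefore demonstrate correctness of the machinery, not
reproduction of the empirical study values, which require the study's own
specimen data and tree.

## Problem sizes

The test suite and acceptance script use sizes chosen to exercise each
property well while staying light: 64-tip trees with 500 Brownian
replicates for the K and type-I calibrations, 200 fits for λ recovery,
999 permutations for single ANOVA fits and 199 inside replicated
calibration loops, 1000 rarefaction replicates (10000 where a Monte-Carlo
median is compared with exhaustive enumeration), and subdivision 3–4
meshes (≈ 6–16 k triangles per surface).

## Known limitations

- The interior-surface contract (exactly one boundary loop) excludes
  valves whose interior meshes carry holes or multiple openings; these are
  rejected, not repaired.
- The minimal-volume alignment helper of the original workflow is not
  included; misaligned meshes yield wrong SL/height/width silently, which
  is why alignment is stated as an input contract.
- λ̂ at the boundary (0 or λ_max) makes the LR test conservative; the
  permutation route is available where that matters.
- The RRPP implementation covers univariate responses only (the scalar
  metrics used here), not multivariate Procrustes data.
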