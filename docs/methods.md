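# Methods

This note documents the models, conventions, defaults, and numerical choices
behind `opermorph`, and what the synthetic data do and do not establish about
behavior on real specimens.

## Outlines and the Φ\* shape function

An outline is an ordered, implicitly closed loop of (x, y) points with a
designated starting landmark (tpsDig convention: the digitizer fixes a
spatially homologous start point, e.g. the curvature maximum on a bone's
dorsal margin; the start point is taken from the file and never re-detected).
Resampling places exactly *p* points (default 100, minimum 8) at equal
arc-length steps along the closed polygon, by linear interpolation of
cumulative arc length, starting exactly at the start landmark. Traversal is
standardized to counter-clockwise via the shoelace sign; clockwise input is
reversed keeping the start point first. No spline smoothing is applied — the
polygon itself is the shape estimate. Resampled points lie on the original
polygon at positions jL/p; consequently the polygon through the resampled
points can be marginally shorter than the original (corner cutting of order
1e-4 relative at p = 100), which is irrelevant downstream because Φ\* uses
the resampled geometry consistently.

The Zahn–Roskies Φ\* function is the cumulative tangent direction of the
resampled loop, unwrapped by accumulating exterior angles in (−π, π] (this
prevents ±2π branch artifacts on concave outlines), referenced to the first
step's direction, minus the turning j·2π/p expected of a circle. Φ\*₀ = 0 by
construction; a regular polygon gives Φ\* ≡ 0 to machine precision. Perimeter
and centroid size are carried alongside as the size variables. Φ\* is exactly
invariant to translation, rotation, and uniform scale.

## Eigenshape decomposition

Specimens' Φ\* vectors form an n × p matrix, column-centered and decomposed
by SVD — equivalent to the eigenanalysis of the covariance matrix of shape
functions. Axes (right singular vectors) are orthonormal; eigenvalues are
squared singular values over (n − 1); scores are projections of the centered
rows. Singular-vector signs are arbitrary, so each axis is flipped to make
its largest-magnitude loading positive, which makes scores reproducible
across runs and platforms. Shape models along an axis integrate unit steps of
length L/p at directions θ₀ + Φ\*ⱼ + j·2π/p and distribute the closure gap
linearly over the points; because the mean of closed-curve Φ\* vectors is
closure-compatible only to second order in the deformations, the round-trip
error of the reconstruction grows with sample variance (≈1e-4 RMS radians for
small-deformation samples, a few times 1e-2 for very heterogeneous ones).

Axis significance uses the broken-stick rule with strict inequality: axis k
(1-based) is significant if its variance fraction exceeds
b_k = (1/p′) Σ_{i=k..p′} 1/i, where p′ counts axes of nonzero variance, and
counting stops at the first failure.

## Phylogeny and ancestral states

Trees are rooted, time-calibrated, read and written as Newick (dendropy
handles parsing; branch lengths are required). Ultrametricity is checked to
1e-6 of depth and violations warn rather than fail. Ancestral states for
phylomorphospace are the maximum-likelihood Brownian estimates, computed as
the solution of the weighted normal equations of squared-change parsimony
(each internal node is the 1/branch-length-weighted mean of its neighbors);
zero-length branches are floored at 1e-12 to keep the system nonsingular.
Species means over specimens are taken before any phylogeny-level analysis;
specimen-level variation enters only the ANOVA/CVA/repeatability statistics.

## Disparity through time and MDI

Disparity is the mean pairwise Euclidean distance among species in ES-score
space (a mean squared-distance option exists, off by default, matching the
other convention in circulation). The DTT curve is evaluated at the sorted
internal-node times: at time t the lineages present are the branches spanning
(t_parent, t_node]; at the root's own time the whole clade is the only
lineage, so the curve starts at exactly 1. Each lineage contributes the
disparity of its descendant tips divided by whole-clade disparity
(single-tip lineages contribute 0), and the values are averaged. The null is
n_sim simulations (default 1000) of multivariate Brownian motion whose rate
matrix is estimated from the score columns by phylogenetically independent
contrasts (sum of uuᵀ/V over contrasts, divided by their count — full
evolutionary covariance, preserving trait correlations). MDI is the
trapezoid-rule signed area between observed and null-median curves over
relative node times ≤ 1 − truncation (default truncation 0.2, omitting the
tip-ward span where incomplete sampling over-disperses tips). MDI is
invariant to rescaling all scores. Clade disparities use per-tip
contributions — each tip's mean squared distance to the others divided by
the sample-wide mean of those values, summed within clade — with a
per-species standardization dividing by the clade's sampled species count;
the per-tip convention is documented here because only the standardization
arithmetic, not the metric, is externally constrained.

## Evolutionary models

All three models are Gaussian on the tips. BM: cov(i, j) = σ²·s_ij with s_ij
the shared path length from the root; parameters (σ², z₀), k = 2. OU
(single optimum, fixed root, optimum tied to the root state z₀):
cov(i, j) = σ²/(2α)·(1 − e^{−2αs_ij})·e^{−2α(T − s_ij)}; k = 3. The
stationary-root variant is deliberately not the default — the fitted optimum
is global and anchored at the root. EB: BM on the transformed tree where a
branch spanning node times (t₁, t₂) has length (e^{at₂} − e^{at₁})/a, a ≤ 0;
k = 3. Likelihoods are evaluated by the linear-time pruning recursion; on
ultrametric trees the OU covariance is realized exactly by the node-height
transform g(t) = (e^{−2α(T−t)} − e^{−2αT})/(2α), so OU reuses the BM
recursion (non-ultrametric trees fall back to dense evaluation with a
warning). α → 0 is handled analytically and reduces to BM.

Fitting profiles z₀ and σ² in closed form at each value of the shape
parameter (the pruning pass yields the GLS mean and σ̂² = SS/n directly), so
only α (in [0, 50/T]) or a (in [log(1e-5)/T, 0]) is searched: a 15-point
log-spaced grid including the BM boundary, refined by bounded scalar
minimization in the bracketing interval. The boundary inclusion guarantees
the nesting logL_OU, logL_EB ≥ logL_BM up to tolerance. Constant traits give
σ̂² = 0 and are reported with `converged = False`, never silently. AICc uses
n = number of tips and the standard correction 2k(k+1)/(n−k−1); model
comparison reports Δᵢ = AICcᵢ − min AICc and weights exp(−Δᵢ/2)/Σexp(−Δⱼ/2).

## Regression and group statistics

PGLS uses generalized least squares with residual covariance proportional to
the Brownian structure (shared path lengths scaled by depth; a species subset
uses the corresponding submatrix — no tree surgery needed). Analyses are run
on complete cases only; the pipeline prunes species lacking isotope values
and logs each exclusion. Two r² flavors are reported because the quantity is
convention-dependent: a likelihood-ratio generalized r²,
1 − exp(−2(logL_model − logL_null)/n), and a GLS sums-of-squares r². The
regression direction is isotope value on shape scores; the overall F-test is
the GLS test of all slopes being zero. Rank-deficient designs fail with the
offending columns named.

ANOVA is standard one-way per axis with df (g − 1, N − g); the per-axis p is
Bonferroni-multiplied by the number of axes tested, and post hoc pairwise
Welch t-tests are Bonferroni-corrected by the number of pairs within each
axis. CVA solves the generalized eigenproblem of between- versus
within-group scatter; min(g − 1, k) canonical functions are returned with
coefficients normalized to unit pooled within-group variance (canonical
scores are then uncorrelated within groups), and successive-root Wilks' Λ
tests use Bartlett's χ² approximation, χ² = −(N − 1 − (k + g)/2)·ln Λ_m with
df = (k − m + 1)(g − m). Repeatability is the one-way ANOVA variance-ratio
R = s²_among/(s²_among + MS_within) with
s²_among = (MS_among − MS_within)/n₀, n₀ the unbalanced-design effective
replicate count, and negative component estimates clamped so R ∈ [0, 1]; R
is invariant to affine changes of the measurement scale.

## Synthetic study design

The generator reproduces the sampling structure of the motivating system:
25 species in 4 clades, 1–12 specimens per species, 100-point outlines, tree
depth 23 time units (My). The tree is pure-birth, conditioned on the tip
count and rescaled to the target depth, hence exactly ultrametric; clades
are the 4 subtrees defined by the earliest splits. Traits default to BM with
σ² = 1/depth (unit variance at the tips) started at 0; OU simulation uses
the fixed-root process with the optimum at the root state, and EB simulates
BM on the transformed tree — exactly the processes the fitting module
assumes. Outlines are a fixed convex Fourier template (curvature maximum at
parameter 0, where the start landmark sits) deformed along one fixed smooth
radial mode in proportion to the species' trait value, with amplitude 0.06
of the template radius — small enough that the Φ\* response is linear in the
trait, giving a known ground-truth ES1. Digitizing error is modelled as
per-point independent radial Gaussian noise (default sd 0.01 of template
radius, ≈0.8 px at the emitted image scale); real digitizing error has no
published distributional description, so this is an explicit assumption.
Isotopes are linear in the trait (δ¹⁵N slope +0.5‰ per trait unit, δ¹³C the
negative, baselines 10.5‰ and −22.5‰, noise 0.4‰), mimicking a
benthic–pelagic axis expressed in both trophic level and carbon source. All
generators are pure functions of (config, seed); outputs are byte-identical
across runs.

**What the synthetic data do not show.** One deformation mode means higher
ES axes carry no biology — tests of ES1 recovery say nothing about resolving
multiple correlated modes. White per-point noise is the harshest plausible
error model for a tangent-angle method: integrating the turning angles turns
white radial noise into smooth, bridge-like Φ\* modes whose variance rivals
the (single) signal mode, so the synthetic digitizing-repeatability R on ES1
is modest and seed-variable, far below the 0.90–0.99 typical of careful real
digitization. This is a property of the noise assumption, not of the R
estimator (which is pinned by exact hand-computed ANOVA cases); with
smoother, correlated tracing error, R rises toward realistic values.
Allometry, ontogeny, 3-D shape, and landmark-based alternatives are out of
scope.

## Problem sizes in routine checks

The test suite exercises the estimators at the scales a desk run affords:
oracle equivalence of the three likelihoods against dense multivariate
normals on 100 random trees of ≤10 tips; parameter recovery on 100-tip trees
over 200 replicates per model (median σ̂² within 10%, median α̂ within 25% at
αT = 3, AICc picking the generating model in a majority); DTT null
self-consistency on a 25-tip tree over 200 replicates with 500 simulations
each (|mean MDI| ≤ 0.05); and null calibration of the ANOVA/Wilks/PGLS
p-values by KS tests against uniformity. The pipeline default of 1000
disparity simulations matches common practice; the acceptance script uses
500.

## Known limitations

- No start-point optimization: if digitized start landmarks are inconsistent
  across specimens, that error enters the shape variables untreated.
- The OU fit does not estimate a separate optimum θ; on data generated with
  θ far from the root state the fitted z₀ absorbs both.
- Wilks' Λ uses Bartlett's asymptotic χ²; very small samples per group will
  show mild p-value miscalibration.
- MDI is reported without a significance test (rank-envelope procedures are
  deliberately out of scope).
- DTT evaluation at internal node times only; no interpolation grid.
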