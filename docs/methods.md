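# Methods

## Shape model

A specimen is an ordered configuration of k = 7 two-dimensional landmarks
at wing-vein intersections around the forewing discal cell. Landmark order
is semantic: index i is the same vein intersection in every wing. Shape is
what remains after removing translation, scale and rotation; reflections
are never removed because all specimens are right forewings and chirality
is informative. Size is summarized by centroid size,
CS = √Σᵢ‖xᵢ − x̄‖², which is independent of shape under isotropic landmark
noise.

### Superimposition

Ordinary Procrustes alignment (OPA) of one shape onto another centres both,
scales both to unit centroid size, and rotates the moving shape by the
proper rotation from the SVD of the cross-covariance (determinant forced
positive). The residual √Σ‖·‖² is the Procrustes chord distance between
the two unit-size shapes, 2·sin(ρ/2) for Procrustes arc ρ; we report this
chord as "Procrustes distance" throughout. At the distance scale of
congeneric wings (< 0.18) the chord, the arc and the classical full
Procrustes distance sin ρ agree to better than half a percent, so the
choice is immaterial at working scale but is stated here for exactness.

Generalized Procrustes analysis iterates: initialize the consensus at the
first specimen (after centring/unit-scaling all shapes); rotate every
shape onto the consensus; recompute the consensus as the coordinate-wise
mean rescaled to unit size; stop when the total Procrustes sum of squares
changes by less than 1e−10 (cap 100 iterations, error on failure). The
initialization is order-dependent but the tolerance removes the dependence
in practice; an explicit test permutes specimen order and requires
agreement to 1e−8. Internally the per-shape rotations use the closed-form
planar optimum θ = atan2(H₁₀ − H₀₁, H₀₀ + H₁₁) (H the 2×2
cross-covariance), which equals the reflection-free SVD rotation and
vectorizes over specimens; the equality is itself under test.

After convergence the whole ensemble is rotated so the consensus principal
axes coincide with the coordinate axes, major axis along x. Only proper
rotations are used here: a single-axis sign flip would be a reflection and
change chirality, so the remaining 180° ambiguity is resolved by rotating
so that consensus landmark 1 (the wing-base landmark) has non-positive x,
with ties broken on y. This makes GPA output deterministic.

Tangent coordinates are the orthogonal projection of each aligned shape
vector v onto the hyperplane normal to the consensus vector c (‖c‖ = 1):
t = v − (v·c)c. For k 2-D landmarks the tangent coordinates span
2k − 4 = 10 dimensions (two translations, one scale and one rotation
removed); the package checks this empirically (eigenvalues above 1e−8 of
the largest) rather than assuming it. Within Procrustes distance 0.2 of
the consensus, tangent and Procrustes distances agree to under 1% (tested),
so Euclidean statistics in the tangent space are faithful at wing scale.

## Statistical engines

All inference happens on tangent coordinates. Permutation p-values use the
(b + 1)/(N + 1) convention — conservative, never exactly zero — and every
analysis draws from a single `numpy` generator seeded by the caller, with
the seed recorded in the results object.

**Shape PCA.** Eigendecomposition of the tangent covariance (divisor
n − 1), components in descending order, eigenvector signs fixed by making
the largest-magnitude loading positive.

**Allometry.** Each tangent coordinate is regressed on centroid size (raw
size by default; a flag switches to log size). The statistic is
`% predicted` = 100 · SS_model/SS_total pooled over coordinates. The
permutation test shuffles the size values among specimens; the statistic is
vectorized over permutations since the size sum of squares is
permutation-invariant. Note the deliberate asymmetry with the generator:
synthetic allometry acts on log size (standard allometric convention,
positive sizes) while the analysis defaults to raw size; with lognormal
size scatter σ_log ≈ 0.08 the raw-size regression caps the recoverable
fraction at corr²(S, log S) ≈ 1 − σ_log²/2 ≈ 99.7%, a mismatch the tests
document rather than hide.

**Procrustes ANOVA.** Centroid size gets an ordinary one-way ANOVA
(df g − 1, n − g). Shape gets Goodall-style F: between- and within-group
Procrustes sums of squares pooled over all coordinates, with both degrees
of freedom multiplied by the shape dimension 2k − 4. p-values come both
from the F distribution and from label permutations; because the total SS
is label-invariant, the between-group SS is a sufficient permutation
statistic and the permutation loop reduces to one matrix product per group.
A cross-check test verifies the two-group identity
SS_B = n₁n₂/(n₁+n₂)·‖m₁ − m₂‖² against the direct decomposition.

**CVA.** The raw 14-dimensional tangent coordinates are rank-10 by
construction, so the pooled within-group covariance is singular there. CVA
is therefore computed in the full-rank PCA subspace (eigenvalues above
1e−8 of the largest). The canonical axes solve the generalized eigenproblem
of between- versus pooled within-group scatter; scores are scaled to unit
pooled within-group variance; n_cv = min(g − 1, subspace rank). Group
separation is reported three ways: Mahalanobis distances under the pooled
within-group covariance, Procrustes distances between group mean shapes,
and per-pair permutation p-values. The permutation statistic is the
squared tangent-space distance between the two permuted group means —
rank-equivalent to permuting the Procrustes distance in the small-variation
regime, and vectorizable; Mahalanobis-based permutation would require a
covariance inversion per draw for no change in the decision at this scale.
The overall test is the Goodall F of the same grouping, so the ANOVA and
CVA headline statistics agree by construction, as they do in standard
morphometric software. An independent test checks that the two-group CV
axis is collinear with Fisher's linear discriminant computed by
scikit-learn (cosine > 1 − 1e−6).

## Screening

`fit_screening_model` freezes the training consensus, tangent mean, PCA
basis, CV axes, group means and within-group score covariance into a
versioned JSON document. A query wing is aligned to the frozen consensus
by OPA (no GPA refit — deterministic, mirrors survey deployment where the
reference is fitted once), tangent-projected, pushed through the stored
subspaces, and assigned to the nearest group by Mahalanobis distance. The
call is flagged ambiguous when the runner-up distance is within 10% of the
smallest (configurable); an explicit ambiguous category matters in triage
because occasional specimens of one species sit inside the other's cluster.
Stored arrays are contiguous copies so that a saved-and-reloaded model
follows the identical BLAS paths and reproduces predictions bit-for-bit.

Reliability is estimated by leave-one-out cross-validation, refitting GPA
and the classifier without each held-out wing. Leave-one-out (not k-fold)
because reference samples can be as small as ~23 wings per species.

## Synthetic data

The generator emulates what the analyses assume about digitized wing data:

- **Templates**: fixed 7×2 mean shapes at unit centroid size. `base_wing`
  sketches a plusiine discal cell; `widened_cell` displaces landmarks 5–7
  outward (Procrustes distance ≈ 0.127 from base — the scale separating
  congeneric species); `narrow_base` pulls landmarks 1 and 7 together
  (≈ 0.075). `template_pair(d)` rescales the displacement field by root
  finding to hit any requested separation exactly.
- **Noise**: iid isotropic Gaussian per landmark coordinate, in shape
  units. Default σ = 0.01–0.03 brackets the between-species distance scale;
  no published digitizing-error estimate exists for this system, so the
  default is a design choice, flagged as such.
- **Sizes**: lognormal centroid sizes (median 600 px, σ_log = 0.08 —
  a plausible spread for wings imaged at fixed magnification), with
  optional additive offsets of mean log size per group.
- **Allometry**: optional 2k-vector per unit log size. The helper
  `orthogonal_shape_vector` builds a unit direction orthogonal to the
  similarity directions at the template (translations, scaling, rotation
  generator) so an injected amplitude survives superimposition with its
  norm intact; the expected explained fraction against the 10-dimensional
  noise floor is then A²σ_log² / (A²σ_log² + 10σ²), which the recovery
  tests invert to inject a nominal 16%.
- **Similarity jitter**: random rotation, translation and (optionally)
  scale per specimen, drawn from an RNG stream separate from the
  shape/size draws, so toggling jitter changes nothing downstream of
  superimposition (tested to 1e−6).
- **Null dimorphism mode**: both sexes drawn from one template, optionally
  offset in size only — the configuration that should yield a significant
  size ANOVA with a null shape test.

What the generator does *not* emulate: correlated landmark noise, damage
or missing landmarks, digitizer drift between imaging batches, and
non-isotropic within-group shape covariance. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness of the biology to those artefacts.

## Problem sizes and numerical notes

Monte-Carlo suites run at deliberately modest sizes chosen to keep the
full test run around a minute while leaving comfortable statistical
margins: 200 replicates (999 permutations each) for the null calibration
of the permutation ANOVA at n = 20 + 20; 100 replicates at the survey-like
n = 194 + 56 for the size-only dimorphism pattern; n = 200–300 per group
for parameter recovery. The permutation engines are vectorized (group sums
as matrix products; pairwise tests chunked at 2000 permutations to bound
memory), so production-scale 10 000-round tests cost well under a second
at these n.

Numerical conventions: GPA tolerance 1e−10 on the change in total
Procrustes SS; rank threshold 1e−8 relative to the largest eigenvalue;
eigenvalue clipping at zero after `eigh`; eigenvector and CV signs fixed
by the largest-magnitude-loading-positive rule; degenerate configurations
(all landmarks coincident) rejected at construction.

Two sampling-theory points that shape the tests: (i) sorted sample
eigenvalues of an isotropic covariance spread deterministically by the
Marchenko–Pastur factor (1 ± √(p/n))², about ±30% at p = 10, n = 500, so
the sphericity check runs at n = 5000 where a 15% band is attainable;
(ii) the Procrustes distance between an estimated group mean and its
template scales as σ√(dims/n) with dims = 10, and the convergence test
uses a 3·σ√(10/n) bound.

## Known limitations

- 2-D landmarks only; no semilandmarks, sliding, or thin-plate-spline
  warps (wireframe plots only).
- The TPS reader accepts the tpsDig dialect (LM=, IMAGE=, ID=, SCALE=,
  unknown keys warned and skipped); other morphometric formats are out of
  scope.
- CVA assumes a shared within-group covariance; no quadratic discriminant
  or jackknifed discriminant-function variant is provided.
- The screening model classifies in CV space (at most g − 1 dimensions),
  which is optimal under the shared-covariance assumption but discards
  within-subspace directions that a quadratic rule could exploit.
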