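# Methods

This note documents the statistical model behind each stage of the
pipeline, the conventions adopted where the geometric-morphometrics
literature admits more than one, and what the synthetic-data generator does
and does not emulate.

## Landmark scheme and data model

A configuration is a 239 × 3 real matrix in mm. The packaged scheme has 57
fixed landmarks and 182 curve semi-landmarks; 45 points lie on the
midsagittal plane and the remaining 194 form 97 left/right antimere pairs.
Scheme validation enforces that the pairing is a perfect matching (an
involution with one left and one right member per pair) and that
semi-landmarks of a curve occupy consecutive slots. A missing landmark is a
NaN row; partially recorded points are normalised to fully missing.

Semi-landmarks are **not slid** along their curves: no sliding criterion
(bending energy vs. Procrustes distance) is part of the default pipeline,
and all points are treated as fixed during superimposition. An analysis
that slides semi-landmarks will shift variance shares by a few percentage
points; the no-slide convention was chosen as the most reproducible
default and is recorded in every run manifest.

## Missing-landmark estimation

Order matters and mirroring comes first: a missing bilateral point whose
antimere is present is reflected across the specimen's midsagittal plane,
estimated as the least-squares plane through its present midline landmarks
(smallest principal axis of their scatter; at least 3 non-collinear points
required). Mirroring inherits the specimen's own asymmetry scale — on an
exactly symmetric configuration it is exact.

Whatever mirroring cannot fill (midline points, pairs missing on both
sides) is estimated by a 3D thin-plate spline with kernel U(r) = r, the
volumetric analogue of the classical r² log r surface spline. The spline
maps the sample average configuration onto the specimen: the specimen's
present points are first similarity-aligned (translation + rotation +
scale) onto the reference — TPS is not similarity-invariant, so alignment
must precede warping — the interpolant is fitted on the present points,
evaluated at the reference's missing-point positions, and the estimates
mapped back to specimen space. The reference starts as the Procrustes mean
of the complete specimens and is refreshed from the completed sample until
the mean shape moves by less than 1e-6 Procrustes distance (max 10
iterations), which makes the initialisation immaterial. Specimens missing
more than a configurable fraction (default 50%) are refused.

Bending energy is reported as |wᵀKw| summed over output dimensions, which
is non-negative on the side-condition subspace and zero exactly for affine
source→target maps.

## Superimposition

GPA centres each configuration, scales it to unit centroid size and
iteratively rotates it onto the running consensus, which is the arithmetic
mean of the aligned shapes (tolerance 1e-10 on the consensus change, max
100 iterations). Conventions:

* **Proper rotations only** (determinant +1). Reflection-invariant matching
  would silently flip specimens and destroy the bilateral-asymmetry
  structure symmetrization relies on; specimens are assumed consistently
  oriented.
* **Consensus initialisation** is the first specimen; determinism requires
  naming one, and the fixed point does not depend on it at tolerance.
* **Canonical frame.** After convergence the whole solution is rotated
  into the consensus's principal-axis frame with a deterministic sign
  convention, so the output is invariant (to 1e-9) under arbitrary rigid
  motion and scaling of any input specimen, including the initialiser.
* **Tangent projection** (default on): aligned shapes are orthogonally
  projected onto the tangent plane at the consensus before ordination.
  Tangent-projected shapes deviate from unit centroid size by O(d²/2),
  about 1e-3 for these data; switch the projection off where exact unit
  size matters.
* **Degenerate input**: configurations whose centred rank is < 2
  (coincident or collinear points) are rejected by name. Planar (rank-2)
  configurations are accepted — the rotation fit remains well defined.

Symmetrization averages a configuration with its relabelled reflection
after a rigid (rotation + translation, no scaling — the two copies have
equal size by construction) Procrustes fit. The result is exactly
object-symmetric about its own midplane and the operation is idempotent;
both properties are tested, not assumed.

Shape distance is the **partial Procrustes distance**: both configurations
at unit centroid size, optimal rotation, root-summed-squared difference —
no re-scaling during the pairwise fit, following the common GPA-literature
convention. Outlier screening flags specimens whose distance to the scope
mean exceeds Q3 + 1.5 IQR of the scope's distances (the upper-whisker rule;
configurable), computed whole-sample or per group.

## Ordination

PCA operates on Procrustes residuals (aligned shapes minus consensus) via
SVD of the centred n × 3k matrix, which is exact under the extreme rank
deficiency here (n ≤ 70 specimens, 717 coordinates). Between-group PCA
diagonalises the covariance of the group mean score vectors — **weighted by
group size** by default (an unweighted option exists) — and projects all
specimens on those axes; at most (groups − 1) axes carry variance.

Leave-one-out cross-validation recomputes group means and bgPCA axes
without each specimen and projects it on the held-out axes. Axis signs are
aligned to the full-data solution per fold (eigenvectors are sign-
arbitrary; without alignment the assembled scores are meaningless). On
groups drawn from a single population CV shrinks apparent group separation
— the well-known self-inclusion bias of plain bgPCA — which the test suite
verifies in expectation.

Group confidence ellipses use the 2 × 2 score covariance with semi-axes
√(λ · χ²₂(level)), level 0.90 by default.

## Distances, permutation tests, allometry

Mahalanobis distances between group centroids use the pooled within-group
covariance. With n ≪ p the pooled matrix is singular, and it is inverted
by Moore–Penrose pseudo-inverse restricted to the data subspace; results
then depend on that convention (tools differ here), which is why the
result object carries a rank-deficiency note. The distance-table builder
pools across all listed groups; permutation tests pool within each pair.

Permutation tests are pairwise: the two groups' specimens are pooled,
labels reshuffled B times (default 10,000), the centroid distance
recomputed, and `p = (#{d ≥ d_obs} + 1)/(B + 1)` — never zero, uniform
under exchangeability. Per-pair RNG streams are spawned from one master
seed in pair order, making every table bit-reproducible and each pair's
p-value independent of which other pairs were requested. For Mahalanobis
and Euclidean metrics the pooled pair is first rotated onto the ≤ n-1
dimensional subspace it spans (distances are invariant to this), which
keeps 10,000 rounds cheap.

The allometry screen regresses each retained PC score on log centroid size
(OLS, two-sided slope test), pooled and optionally per sex (M/M? and F/F?
strata); `no_significant_allometry` summarises the scan at α = 0.05. With
15 PCs × 3 strata the all-clear flag is a joint statement over 45 raw
tests and will fail ~90% of the time on null data by chance alone — it is
reported as the study reported it (raw p-values, no multiplicity
correction), with an optional Bonferroni column available.

## Covariance comparison

Group covariances are computed on the first 6 PC scores (denominator n−1;
the ML variant n is a flag). For a pair (S_a, S_b) the relative
eigenvalues λᵢ — eigenvalues of S_b⁻¹S_a, computed by the generalized
symmetric eigenproblem — yield:

* the ML proportionality statistic
  `T = n_eff (k log λ̄ − Σ log λᵢ)`, with `n_eff = ν_a ν_b/(ν_a + ν_b)`
  (ν = n − 1) combining the two samples, referred to χ² with
  k(k+1)/2 − 1 degrees of freedom. T = 0 iff S_a ∝ S_b exactly. The χ²
  calibration is asymptotic: at n = 200 the empirical type-I rate is
  ≈ 0.05 (verified by simulation in the test suite); at n = 11 — the
  study's group size — the test is markedly anti-conservative, as any
  likelihood-ratio test is at such sizes.
* the generalized-variance ratio det(S_a)/det(S_b) = Π λᵢ. Note that a
  6-dimensional log-determinant estimated from n = 11 carries a standard
  error of ≈ 1.6, so single-sample ratios scatter over more than an order
  of magnitude around the truth; only order-of-magnitude gaps in the
  ratio table are individually meaningful at that sample size. The test
  suite therefore checks ratio recovery on geometric means over replicate
  simulations at n = 100.

Exclusion re-runs (e.g. dropping one outlier) recompute only the affected
group's covariance; comparisons not involving it are unchanged.

## Synthetic-data generator

`simulate()` draws each specimen as

    template + group offset + within-group deviation
             + allometric shift + bilateral asymmetry,

then applies a lognormal size, a uniform random rotation and a random
translation, and finally deletes landmarks. Components:

* **Template**: a deterministic, exactly bilaterally symmetric
  cranium-proxy (ellipsoidal vault plus projecting midsagittal face
  profile), unit centroid size — a function of the scheme, so no binary
  fixture is needed. It is a statistical scaffold, not an anatomical
  model.
* **Shape subspace**: an orthonormal basis of symmetric directions
  orthogonal to the template, to translations and to infinitesimal
  rotations, so a planted offset of norm d survives superimposition as a
  Procrustes distance of d (to second order). Within-group deviations are
  drawn in this basis with an eigenvalue spectrum (isotropic, geometric
  decay, or factor model) of total scale σ (default 0.035, a typical
  human within-group cranial dispersion).
* **Generalized variance**: each group's covariance is multiplied by
  `gv_scale^(1/6)` per axis, so the determinant ratio of any common
  6-dimensional projection — in particular the 6 PCs the variance
  analysis retains — equals the planted `gv_scale` ratio, regardless of
  how PCA rotates the subspace.
* **Asymmetry**: an antisymmetric Gaussian field (the symmetric component
  is projected out), default 0.0005 shape units ≈ 0.6 mm per coordinate
  at a 1150 mm centroid size — the sub-millimetre scale of cranial
  fluctuating asymmetry. Symmetrization removes it by construction.
* **Size and allometry**: log CS ~ Normal(log size_mean, (size_sd/
  size_mean)²), defaults 1150 ± 40 mm for a 239-point cranium; an
  optional slope couples shape to log CS along a fixed direction.
* **Planted outliers**: a named specimen's within-group deviation is
  rescaled to exactly m × the group RMS magnitude (random direction), so
  outlier tests do not hinge on the tail luck of one draw.
* **Missingness**: random or bilateral-biased deletion with a per-specimen
  cap.

`replay_study_design()` instantiates the published design: five fossil
groups (n = 4, 4, 7, 5, 6, with the published specimen ids and sexes —
42.3% female counting uncertain attributions) plus four extant groups of
11 (4 females each, 36.4%); 18 specimens (13 fossil, 5 extant) lose < 20%
of their landmarks; variation spans 30 dimensions with spectrum decay
0.85, chosen so the PC-share profile resembles real cranial samples
(PC1–3 ≈ 40–55%, 6 PCs ≈ 60%, 15 PCs ≥ 90%) rather than collapsing onto a
handful of axes; relative generalized variances follow the published
ordering (AmNat 1.0 > LUP 0.70 > MUP 0.22 > EuS 0.11 > Inuit 0.034 >
OcPap 0.004); the two MUP subsamples share one mean direction (they
emulate a single homogeneous paledeme — the study's central finding)
while the two LUP subsamples, two different techno-complexes, get
independent offsets; specimen DV3 is planted as a mild (2.5 × RMS)
within-group outlier. Allometric slope is zero, matching the reported
absence of a size effect.

What the generator does **not** emulate: anatomical growth constraints,
spatially correlated digitising error, curve-structured semi-landmark
covariance, taphonomic (non-random) damage patterns beyond the
bilateral-biased option, and inter-observer landmarking error. Passing
tests on generator data therefore validate the statistical machinery —
recovery of planted offsets, variances, slopes and outliers through the
full imputation → symmetrization → GPA → ordination chain — not the
anatomical fidelity of any particular fossil result.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 70-specimen,
239-landmark design with 10,000 permutation rounds (seconds to tens of
seconds); simulation-based calibration tests use 200–500 replicates at the
sizes stated in each test (uniformity of permutation p at n = 8 + 8,
proportionality type-I at n = 200, slope coverage at n = 70, gv-ladder
recovery at n = 100). Statistical acceptance checks on noisy statistics
average over replicates and use binomial envelopes rather than asserting a
single draw. Key tolerances: GPA consensus change 1e-10; TPS reference
fixed point 1e-6 Procrustes; pseudo-inverse rcond 1e-10; p-values carry
the +1 correction. All randomness flows from named integer seeds through
`numpy.random.SeedSequence` spawning, so every table is bit-reproducible.

## Known limitations

* Printed Mahalanobis distances from studies using other tool chains are
  reproducible only up to the pseudo-inverse convention; orderings are
  stable, magnitudes need not be.
* The proportionality test's χ² reference is unreliable below n ≈ 30 per
  group; p-values at n = 11 should be read as descriptive.
* No semi-landmark sliding; no mesh-based surface deviation maps (the
  per-landmark deviation field is the supported analogue); no
  reflection-invariant matching; no missing-data GPA (imputation is
  upstream and explicit).
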