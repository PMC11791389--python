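# Methods

This note documents the models, conventions and numerical choices behind
`allotraj`, in the spirit of the methods appendices of mature
statistical packages. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and filtering

A dataset is a collection of specimens, each a k×d landmark
configuration in mm annotated with species (`Genus_species`) and sex
(F/M). Genus is always derived from the species label — a single source
of truth. All analyses run per sex: adult size–shape covariation should
not be conflated with sexual dimorphism, which is large and variable in
cercopithecid monkeys. Within a sex, species enter an analysis only if
they have at least `min_n` specimens of that sex (10, 20 or 30); the
filter is per-sex, so a species can qualify for females and not males.
Each (sex, threshold) dataset is re-superimposed from raw coordinates —
alignments are never shared across analysis datasets. Applied to the
packaged museum-survey counts (78 species), the per-sex ≥10 rule keeps
2942 of 3221 specimens; both numbers are asserted in the tests.

TPS is the interchange format (dialect: `LM=`/`LM3=` count line,
coordinate lines, required `ID=`, optional multiplicative `SCALE=`);
metadata is CSV keyed by `specimen_id`; trees are Newick chronograms
with branch lengths required and tip labels normalized to underscore
form.

## Superimposition and shape variables

Full generalized Procrustes analysis: center, scale to unit centroid
size, rotate each configuration to the current mean with the optimal
*proper* rotation (reflections are anatomically meaningless and
disallowed), re-estimate the mean, re-scale it to unit size, iterate.
Convergence tolerance is 1e-10 on the mean-shape change with a 100
iteration cap; a final rotation pass leaves every configuration
optimally rotated to the reported mean. Centroid sizes are recorded
before scaling; lnCS is their natural log.

Shape variables are the principal components of the aligned-coordinate
residuals about their mean, orthogonally projected onto the tangent
plane at the (unit-size) Procrustes mean before the PCA. The projection
matters for a precise dimensional claim: without it, the residual radial
direction retains a tiny O(scatter²) variance and the shape space has a
spurious extra dimension at fine tolerance. With it, exactly 2k − 4
components carry variance for generic 2D data (translation ×2, scale and
rotation each consumed by the superimposition) — 8 dimensions for the
6-landmark cranial configuration. Components with eigenvalue below
1e-10 × the largest are dropped; each retained component's
largest-magnitude loading is made positive so outputs are reproducible
across platforms. Consequences of the projection are auditable rather
than assumed: `distortion_check` reports the matrix correlation between
tangent (score) distances and pairwise partial-Procrustes chord
distances, which exceeds 0.99 at realistic cranial shape scatter (and
equals 1 to 1e-12 against the projected residuals themselves, since the
retained PCs are a complete orthonormal basis for them).

`midplane_project` handles nominally midplane 3D input: least-squares
plane through the centroid via SVD, orthogonal projection, orthonormal
in-plane basis with a deterministic sign convention; collinear
configurations are rejected.

## Static allometry

Within one species and sex, all m shape PCs are regressed on lnCS by
ordinary least squares (one shared predictor; fitting is per species
with no pooling and no mixed models, and always on the full PC set —
never a truncated subspace). Reported per fit:

- slope and intercept vectors (shape units per unit lnCS);
- trace-based multivariate R² — model sum of squares summed across
  responses over total — the "shape variance explained" convention,
  *not* 1 − Λ;
- Wilks' Λ = |E|/|E+H| with E, H the residual and model cross-product
  matrices, computed via `slogdet` for stability. With a single
  predictor Rao's transform is exact: F = ((1 − Λ)/Λ)(df₂/df₁) with
  df₁ = m, df₂ = n − m − 1, so no approximation hierarchy is needed. A
  numerically singular E (perfect fit) maps to Λ = 0, p = 0.

A fit is *non-negligible* when p < α (default 0.005) **or** R² > 0.05.
Species with n ≤ m + 1 are reported as untestable and excluded from
angle analyses — never silently dropped. Calibration is part of the
acceptance suite: under a simulated null the rejection rate at α = 0.005
stays within binomial error over 2000 fits, and the fitted quantities
match an independent normal-equations/determinant oracle to 1e-8.

For visualization, predicted shapes at a species' observed lnCS extremes
are reconstructed through the PC basis with the deviation from the
species mean multiplied by a magnification factor (default 3) — static
allometric displacement is small and invisible unmagnified. A single
summary axis for cross-species plots is obtained by pooling per-specimen
predictions and projecting on the unit vector in their span that
maximizes covariance with lnCS (the regression-score construction); the
fraction of prediction variance on that axis is reported.

## Trajectory divergence

Divergence between two species is the angle between their slope vectors:
arccos of the normalized dot product (argument clipped to [−1, 1]),
in degrees. Direction sense is retained — angles run to 180°, treating
trajectories as oriented; empirically obtuse angles occur and folding at
90° would hide them. Angles are computed only within one sex and one
threshold dataset, over species passing the non-negligible rule, in
alphabetical species order.

Summaries use mean, sample SD, median, 10th/90th percentiles and range
over the strictly-lower-triangle pairs. The quantile rule is linear
interpolation of order statistics at h = (n − 1)p + 1 (the default of
the common statistical environments), noted here because percentile
conventions differ across software. Medians are also split by whether
the two species share a genus; empty partitions are reported as
undefined (NaN), never zero, and the pair counts are always attached
because within-genus sets can be as small as one pair.

UPGMA phenograms are built with average linkage on the angle matrix;
node heights are half the merge distance, so the tree is ultrametric by
construction, and ties are broken by alphabetical order of cluster
labels for reproducibility. The implementation is cross-checked in the
tests against scipy's average-linkage cophenetic distances. Cophenetic
correlation with the input is reported, never asserted — a phenogram is
a summary, not a test.

## Phylogenetic signal

Patristic distances are summed branch lengths between tips of the
chronogram (tree handling via dendropy; data and tree are intersected
with `match_taxa`, which logs what is dropped on either side and
requires at least 3 shared species). The angle–patristic association is
a plain Pearson matrix correlation of lower triangles, deliberately
without a permutation test — it is reported as a descriptive effect
size only.

Significance testing uses the multivariate extension of Blomberg's K:

K = [tr(YcᵀYc) / tr(Ycᵀ C⁻¹ Yc)] ÷ [(tr C − s/(1ᵀC⁻¹1)) / (s − 1)],

where C is the Brownian tree covariance (shared root-to-MRCA path
lengths), and Yc centers the traits on the generalized-least-squares
root state a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y. K = 1 matches the Brownian
expectation on the given tree; K → 0 means no signal. The permutation
test shuffles trait rows across tips, with p = (b + 1)/(m + 1) so p is
always valid in (0, 1] at finite permutations (1000 by default, seeded
and bit-for-bit reproducible). C is used as-is from the chronogram —
K is invariant to a global rescaling of C, so unit-height normalization
would be cosmetic. A warning is emitted below 20 species, where the
permutation test is known to have little power; the test is one-sided
for the *presence* of signal and says nothing about K ≠ 1.

Because K cannot consume an angle matrix directly, the angle matrix is
first embedded by principal coordinates analysis: Gower double-centering
of −½D², eigendecomposition, axes with eigenvalue above 1e-8 × the
largest retained, coordinates scaled by square-rooted eigenvalues.
Angle matrices need not be Euclidean; negative-eigenvalue axes are
dropped and counted (logged), with no Cailliez/Lingoes correction — the
dropped count keeps the choice auditable. K is then computed on the full
retained coordinate set.

The mean-shape contrast uses per-species averages of the aligned
configurations: pairwise partial-Procrustes distances between means feed
the matrix correlation and a UPGMA phenogram, while K is computed on the
mean tangent coordinates directly (distances between means are Euclidean
in tangent space to the accuracy established by the distortion check,
so embedding them first would only add noise).

Calibration, again in the suite: univariate K agrees with an
independently coded whitening implementation and with an external R
implementation to 1e-9; K averages 1 (±0.15) over 200 Brownian
simulations on a 20-tip tree; it is exactly 1 on an equal-branch star
phylogeny; and it is invariant under orthonormal rotation of the trait
columns.

## Subsampling experiments

The balanced bootstrapped subsampling experiment isolates the effect of
sample size on angle estimates. Per replicate and species: resample the
species' specimens with replacement back to the original n (the
bootstrap), then draw `target_n` of those draws without replacement (the
selection) — this two-stage reading follows the stated order of
operations, and a one-step alternative (draw `target_n` with replacement
directly) is available behind a flag for sensitivity checks. Every
species contributes exactly `target_n` specimens per replicate, asserted
each time. Slopes are refit on the *fixed* total-dataset score basis —
angles are only comparable within one coordinate system, and the
observed reference angles live in that space; whether to re-superimpose
per replicate is genuinely open, and the fixed-basis choice is the
logged assumption. Replicates that draw a degenerate sample (constant
lnCS) are redrawn and counted. After 100 replicates (default), the
per-pair median angle minus the observed total-sample angle is the bias
estimate; summaries use the same statistics and quantile rule as the
angle tables. A diagnostic mode (bootstrap off, `target_n` = total n)
reproduces the observed angles exactly and anchors the identity test.

The acceptance experiment (50 seeded runs of 6 species × 60 specimens)
shows the expected structure: mean bias positive at every target n,
roughly doubling from N = 30 to N = 10, with the SD of per-pair
differences non-decreasing as n falls and individual pairs occasionally
*under*estimated even when the mean bias is positive.

## Synthetic data generator

The generator is the package's fixture factory and defines the regime in
which the pipeline is validated. Simulation happens in the 8-dimensional
tangent space at a fixed hexagonal 6-landmark template (a stylized
midplane cranial wireframe), through an orthonormal basis constructed as
the complement of the template's translation, scaling and rotation
directions — so true slope vectors are exactly representable in the
analysis space and recovery error is attributable to sampling alone.

Per species, mean shapes evolve by Brownian motion (rate
`sigma_bm_mean`, default 0.02 per tangent component per unit tree depth)
on a supplied tree or a pure-birth (Yule) simulation scaled to unit
depth. Slope vectors are a shared base trend (norm 0.063, fixed
direction) plus √(signal_mix)·BM(`sigma_bm_slope` = 0.018) +
√(1 − signal_mix)·iid noise of matched marginal variance — the mix dial
moves phylogenetic signal without changing slope magnitudes. Specimens
draw lnCS ~ N(species mean, 0.15) with species means spaced over
lnCS 4.2–5.2 (centroid sizes ≈ 67–180 mm), add slope·(lnCS − mean) plus
isotropic tangent noise (`sigma_residual` = 0.01), and are emitted at
true size (centroid size exactly exp(lnCS)) under a random proper
rotation and bounded translation so the superimposition is genuinely
exercised. Per-species random streams derive from the master seed as
`SeedSequence([seed, 1 + species_index])`; regeneration is
byte-identical.

The defaults place within-species R² near 10% at moderate n (the
expected value |b|²σ²_lnCS / (|b|²σ²_lnCS + mσ²_res) ≈ 0.10, varying
roughly 3–30% across species as slopes evolve) and pairwise angles at a
few tens of degrees — the moderate-effect regime static cranial
allometry actually occupies. What the generator does *not* emulate:
measurement error structure, sexual dimorphism (sexes are generated as
independent datasets), non-linear or multiphasic allometry, landmark
digitization bias, or non-Brownian evolutionary models. Tests passing on
these fixtures therefore validate the estimators and their sampling
behaviour, not the biological claims one might make from real data.

Noise-free recovery is exact only in the linear tangent limit: with zero
residual noise the specimens trace a slightly curved image of the
allometric line on the shape sphere, and the fitted direction deviates
from the truth linearly in the size spread (≈0.008° at lnCS SD 0.01).
The recovery tests are therefore run inside that regime, with the
moderate-noise, large-n case covering the realistic one.

## Experiment sizes and determinism

Default problem sizes — 6–12 species, 30–60 specimens per species,
100 bootstrap replicates, 50-run experiment batteries, 200-replicate
calibrations — were chosen so the full validation battery completes in
well under a minute each while leaving Monte-Carlo margins comfortably
wide; all stochastic steps take explicit seeds and are reproducible
bit-for-bit. The signal-recovery experiment pairs its runs with common
random numbers (both members share the tree and seed, differing only in
whether slope deviations follow it) and uses 12 taxa, since K
discriminates poorly on very small trees.

## Known limitations

- The multivariate regression requires n > m + 1; with 8 shape PCs the
  minimum usable species sample is 10, which is exactly the loosest
  inclusion threshold — error degrees of freedom are then 1 and the
  Wilks test is weak, which is part of why small-sample angle estimates
  are noisy.
- The permutation test for K has low power below ~20 taxa (warned at
  runtime); non-significant K on small trees is not evidence of absence.
- Angle matrices are generally non-Euclidean; dropping negative PCoA
  eigenvalues discards a (logged) fraction of squared distance.
- UPGMA assumes ultrametric-like similarity structure; it is used as a
  display summary only.
- The TPS reader supports the common dialect only (no IMAGE-based
  scaling chains, no curves/outlines).
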