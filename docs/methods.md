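# Methods notes

This note documents the statistical procedures, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Superimposition

Partial Procrustes superimposition is used throughout: every
configuration is centred and scaled to unit centroid size, and only a
proper rotation is fitted (reflections are disallowed because all wings
are digitized on the same body side). The alternative — full Procrustes
with cos ρ shrinkage — changes tangent coordinates only at second order
for the small shape variation typical of wing data; the unit-CS
convention keeps the invariants simple (every aligned shape has |CS − 1|
< 1e−9 exactly).

The GPA iteration alternates rotating all shapes to the consensus with
re-estimating the consensus as their normalized mean. Two numerical
choices matter:

- **Initialization.** The consensus starts at the normalized mean of the
  centred, scaled shapes rather than at an arbitrary specimen. For data
  that are already mutually aligned the mean *is* the fixed point, so a
  re-run converges immediately (idempotence); an arbitrary-specimen start
  perturbs aligned data and then needs several geometric-decay iterations
  to return. If the mean degenerates (unaligned orientations can cancel),
  the first specimen is used as a fallback.
- **Convergence metric.** Consensus movement is measured modulo rotation
  (the optimal-rotation residual between consecutive consensus
  estimates), because the global orientation of the whole aligned set is
  gauge freedom — it is fixed deterministically afterwards by rotating
  the set so the consensus lies along its principal axes, with a sign
  convention on the first landmark. Tolerance 1e−10 on that residual,
  maximum 100 iterations, warning (not error) on non-convergence.

Tangent projection removes the component of each aligned shape along the
(unit-norm) consensus vector. Centroid sizes reported for the
size–altitude analysis are computed from the raw, pre-scaling
coordinates; this assumes all images share one physical scale (fixed-dpi
scanning, or SCALE= factors applied at read time — the reader applies
them by default).

## Ordination and group statistics

Tangent data are rank-deficient by construction (rank ≤ 2k − 4) and group
sizes can be below the variable count, so the within-group covariance is
regularized by a PCA pre-reduction: keep the smallest number of leading
components reaching `var_retain` (default 0.99) of total variance, capped
at n − g and at the numerical rank. CVA then solves the symmetric
generalized eigenproblem Bv = λWv; eigenvectors are W-orthonormal, which
makes the pooled within-group variance along each canonical axis exactly
one and turns Euclidean distances between group means in canonical space
into Mahalanobis distances. Every fit cross-checks the canonical-space
distances against the direct quadratic form (mᵢ−mⱼ)ᵀW⁻¹(mᵢ−mⱼ) at 1e−8
and fails loudly if they disagree.

D is reported as the distance (D) with the squared scale (D²) alongside,
both explicitly labelled: morphometrics packages differ in which scale
they print, and an unlabelled "Mahalanobis distance 3.5" is ambiguous.

Pairwise permutation tests shuffle specimen labels between the two groups
of the pair only and recompute the full statistic — including the pooled
covariance in a jointly re-reduced subspace — each time. p-values use the
add-one convention p = (1 + #{perm ≥ obs}) / (1 + n_perm), so the
smallest achievable p is 1/(n_perm + 1) and p is never zero. Default
n_perm = 1000, always seedable.

The size–altitude association is an ordinary Pearson correlation with the
two-sided p-value from the t transform on n − 2 degrees of freedom;
significance stars in summaries use p < 0.05 / p < 0.01.

## Classification

The linear discriminant operates in the same PCA-reduced subspace policy
as the CVA, fitted on the reference specimens only. Priors default to
equal because reference panels are balanced by design; proportional
priors are available. Ties in discriminant scores (possible with
duplicated reference classes) are broken toward the lexicographically
first group name with a logged warning.

Leave-one-out cross-validation refits the discriminant — including the
subspace reduction — for every held-out specimen, but does **not** redo
the superimposition: GPA on n − 1 versus n shapes moves the consensus by
O(1/n), which is negligible against within-group variation. This is a
deliberate, documented approximation; redoing GPA per fold would square
the cost for no measurable change at survey sample sizes.

Two operationalizations of "Africanized" are provided, because survey
reports differ in how the hybrid category enters the analysis: (a) the
default argmax mode, where study wings are assigned among the four pure
references and Africanized means assignment to the *A. m.
scutellata*-like reference; and (b) a hybrid-reference mode
(`RunConfig(hybrid_reference=True)`), where the study wings themselves
form a fifth "AB" training class and Africanized means assignment to AB
or to the scutellata-like reference. Neither is asserted as the only
correct reading; both produce the same report structure.

## UPGMA

UPGMA is implemented directly (the merge history, deterministic
tie-breaking, and exact-agreement guarantees are part of the contract):
repeatedly merge the closest pair at height d/2, with the distance from a
merged cluster to any other the size-weighted average of its parts —
equivalently, the arithmetic mean of all between-cluster leaf-pair
dissimilarities. Ties break toward the lexicographically smallest pair of
cluster keys (sorted leaf tuples), making the merge order reproducible
across platforms. The placebo outgroup gets no special rooting logic: it
simply joins last because its distances dominate. Newick output carries
branch lengths at 10 significant digits and round-trips through standard
tree parsers with heights preserved to 1e−9.

## Haplotype assignment

Queries are aligned globally (Needleman–Wunsch; match 1, mismatch 0, gap
−1, linear gap penalty) against a user-supplied panel; identity is
100 × matches / alignment columns with gap columns counted in the
denominator — a conservative "global identity" stated explicitly because
report conventions vary. `N` is scored as a mismatch and never counts as
an identity match (configurable). Optimal global alignments are not
unique and can differ in match counts, so the identity is defined over
the optimal alignments that also maximize matches; this is achieved by a
scaled match bonus that cannot alter the primary optimum for
integer-valued scores, and it makes identity symmetric in its arguments.
Best-hit assignment reports the runner-up and margin, warning below 0.5
percentage points; exact ties go to the lexicographically first
haplotype name. Typical amplicon lengths (400–740 bp) are soft-validated
with a warning only.

## Synthetic data generator

The generator emulates the *statistical* structure of a highland
Africanization survey, not wing biology:

- **Design**: 4 reference panels × 50 wings, 15 apiaries × 5 colonies ×
  10 wings (750 study wings), optional placebo outgroup (n = 10), k = 19
  landmarks.
- **Shapes**: a fixed ring-like base outline; reference means are the
  base plus random tangent offsets of norm `separation` (default 0.06),
  orthogonal to the similarity-transform directions; specimens add
  isotropic Gaussian tangent noise (SD `sigma_w`, default 0.015 per
  coordinate). Study wings are mixtures of the reference means with
  weight λ (default 0.9) on the *scutellata*-like mean — one dominant
  hybrid morphotype overlapping that reference. The placebo mean sits at
  10× separation. Defaults were fixed once from the survey design being
  emulated; separation/noise were chosen so reference panels separate by
  several pooled SDs while the hybrid cloud genuinely overlaps its
  nearest reference.
- **Size model**: CS = β₀ + β₁·altitude + ε with β₁ and σ_ε calibrated so
  that, for altitudes uniform over 2600–3274 m (15 contiguous apiary
  bands), the population altitude–CS correlation equals ρ (default
  −0.32) and SD(CS) = 0.35 around a mean of 7.5 (arbitrary but fixed
  image units).
- **Nuisance**: each emitted configuration is randomly rotated and
  translated; its scale *is* its centroid size, so the pipeline must
  genuinely undo position/orientation/scale. A further independent
  per-specimen scale jitter is deliberately not applied: it would model
  uncalibrated imaging and destroy the size signal the survey measures
  (real surveys scan at fixed resolution or calibrate via SCALE=).
- **Sequences**: a random base sequence mutated at 5% per haplotype gives
  a panel of ~≥5% mutually divergent named haplotypes; queries mutate a
  panel member i.i.d. at a chosen rate, with truth retained for scoring.

What the generator does **not** emulate: real vein-intersection
geometry, published subspecies mean shapes, landmark-specific error
covariance (noise is isotropic by default), shape–altitude coupling
(size-only by default; a flagless extension point), colony-level random
effects, and sequence indel polymorphism (substitutions only). Passing
tests therefore demonstrate the correctness and calibration of the
*procedures*, not field-realistic effect sizes.

## Problem sizes used in checks

The automated checks run at the survey's native scale where that is cheap
(750 + 200 + 10 specimens, k = 19; 200 correlation replicates at n = 750;
1000 haplotype queries) and at reduced scale for the heavily replicated
calibration experiments (e.g., permutation calibration at 500 replicates
× 199 permutations on n = 20 + 20, 5-variable data). These sizes are the
package's own choices for tight, reproducible statistical tolerances.

## Known limitations

- 2-D landmarks only; no semilandmarks, no thin-plate-spline deformation
  displays.
- The CVA regularization (PCA pre-reduction) is one of several defensible
  choices (ridge shrinkage, pseudo-inverse); `var_retain` is exposed.
- LOO-CV keeps the superimposition fixed (see above).
- Haplotype identity against a local panel is not equivalent to a BLAST
  search of a public database; percentages depend on the panel provided.
- UPGMA assumes rate-like (ultrametric-ish) divergence of group means;
  it is a display convention here, not a phylogenetic estimate.
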