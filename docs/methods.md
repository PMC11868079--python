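# Methods

## Model

The classifier assumes that, after selecting a small attribute subset, the
two classes of a numeric binary dataset are separable by a radial
(spherical) frontier: one class concentrated near the origin of the
selected subspace, the other outside it. Learning composes elementary,
fully deterministic steps; there is no iterative fitting.

**T-means scoring.** For attribute *j* with class column means `m1[j]`,
`m2[j]`, the threshold is `T[j] = (m1[j] + m2[j]) / 2`. Error vector
`E1[j]` counts class-1 values strictly above plus class-2 values strictly
below `T[j]` (hypothesis: class 1 below); `E2[j]` is the mirror. Values
exactly equal to the threshold count in neither vector, so for every
attribute `E1[j] + E2[j] + (#values equal to T[j]) = n1 + n2`.

**Orientation.** `C1_IN = mean(E1) < mean(E2)` (strict; a tie yields
False). `C1_IN` simultaneously selects which error vector ranks the
attributes (E1 when True) and on which side of the spherical boundaries
class 1 is modeled (inside when True). The orientation convention is the
one consistent end-to-end with the voting rule below: `C1_IN = 1` means
class 1 below the thresholds, ranked by E1, inside the boundaries.

**Two-stage attribute selection.** Stage 1 keeps the `att` attributes
with the smallest chosen error counts (stable sort, ties broken by
ascending attribute index — a deterministic convention). Stage 2 scores
each kept attribute with a 1-D radial boundary: the radius of a single
value is |value|, the boundary is the midpoint of the adjacent class
extremes (`(max r1 + min r2)/2` with class 1 inside, the mirror
otherwise), and the score is its resubstitution error, again with strict
inequalities so radii exactly on a boundary are errors for neither class.
Attributes are re-ranked by this score; the reported training error is
the minimum score. Only the first `bound` re-ranked attributes enter the
model — the stage-1 pool exists to give stage 2 a cheap, already-plausible
candidate set.

**Progressive boundaries.** For k = 1…`bound`, every training pattern is
reduced to the radial norm of its first k re-ranked attributes (prefix
norms are non-decreasing in k), and a boundary placed at the midpoint of
the adjacent class extremes of those norms. The model is `C1_IN`, the
ordered learning attributes, and the boundary vector.

**Classification.** A test pattern is projected onto the learning
attributes (attributes outside the model are ignored entirely), prefix
norms computed, and each boundary casts one vote: class 1 iff
`norm < boundary` when class 1 is inside, `norm > boundary` when outside;
equality votes class 2. Class 1 is assigned iff its votes reach at least
`bound / 2` — with an even vote count, an exact half suffices, a literal
reading of the voting rule that also keeps the single-boundary case
consistent.

Only the radial component of the N-spherical transform participates in
decisions; the angular components (each an arccos in [0, π], so the sign
of the last coordinate is not recoverable) are provided for inspection.

## Hyperparameter self-adjustment

`att` and `bound` are tuned by integer Differential Evolution minimizing
the training error. Defaults: population 20, mutation factor F = 0.5,
recombination probability pR = 0.9, 30 generations, `att` in
[1, min(L, 200)], `bound` in [1, 15] — canonical small-budget DE settings
for a two-integer search space. Trial vectors `x_c + F (x_a − x_b)` are
rounded half-away-from-zero (deterministic across platforms), clamped
into bounds and repaired to `bound ≤ att`; replacement is greedy (strictly
smaller training error). Binomial per-coordinate crossover with one
guaranteed mutant coordinate is the default; an all-or-nothing `gate`
variant, in which pR gates the whole trial evaluation and coordinates are
never mixed, is selectable. Out-of-range integers produced by the
arithmetic are clamped with a warning rather than rejected, keeping the
metaheuristic loop total. With a fixed seed the whole loop is
bit-reproducible; evaluated (att, bound) pairs are cached, which changes
nothing observable.

## Evaluation protocol

Leave-one-out cross-validation is used because it is deterministic. The
held-out pattern is excluded from *every* learning computation: column-mean
imputation of missing values is recomputed on each training fold and then
applied to the held-out pattern. With a `DEConfig`, hyperparameters are by
default retuned inside every fold (each fold derives its own seed from the
base seed); a `global` mode that tunes once on the full data is provided
for speed and is explicitly optimistic, since tuning then sees the
held-out patterns. Class 1 is the positive class: balanced accuracy is
the mean of sensitivity and specificity (invariant under duplicating one
class's outcomes), F1 is `2tp / (2tp + fp + fn)`, defined as 0 when
tp = 0 with errors present and undefined when all counts are 0.

## Classifier comparison statistics

Scores (higher = better) are converted to within-dataset midranks
(rank 1 best, ties averaged; every row sums to k(k+1)/2). The Friedman
statistic is the classic chi-square form
`12/(N k (k+1)) Σ_j Rsum_j² − 3N(k+1)` with k−1 degrees of freedom — no
tie correction and no Iman–Davenport transformation, so the p-value on
matrices with many ties is approximate (on tie-free matrices it agrees
with `scipy.stats.friedmanchisquare` to machine precision, which the test
suite checks). Holm's step-down post-hoc compares every algorithm with a
control (default: best mean rank): `z_i = |R_ctrl − R_i| / SE` with
`SE = sqrt(k(k+1)/(6N))`, two-sided normal p-values, thresholds
`α/(k−i)` down the table sorted by descending z, and rejection stopping
at the first non-rejection.

A 13 × 7 balanced-accuracy benchmark matrix ships with the package
(`spheremml/data/benchmark_balanced_accuracy.csv`) so the comparison
machinery is exercisable without any external download.

## Synthetic data: what it emulates and what it does not

`radial_shells` realizes the model's separability premise exactly:
the inside class uniform in a ball of radius `inner_radius` (Gaussian
direction × U^(1/d)-scaled magnitude, correct uniformity in any
dimension) over the informative dimensions, the outside class with each
informative coordinate drawn uniformly from
`[outer/√d, 2·outer/√d]` in the positive orthant — so each outside
pattern's radial norm lies exactly in `[outer, 2·outer]`. The one-sided
(positive-orthant) construction is deliberate: it gives every informative
attribute both a class-mean gap (detectable by the T-means threshold) and
1-D radial separability (so the stage-2 score reaches zero). A
sign-symmetric shell would have per-attribute class means both ≈ 0 and
would defeat any univariate mean-based score, making selection of the
informative attributes impossible in principle for this model class.
Noise columns are standard normal, identically distributed in both
classes, hence informative-free by construction — which is what makes
"selected attributes ⊆ informative set" a checkable parameter-recovery
assertion. Defaults (n1 = n2 = 15, 3 informative + 50 noise dimensions,
inner radius 1, outer radius 5) give an ample-margin regime in which
learning is exact: zero training error, recovered orientation, perfect
LOOCV balanced accuracy.

`gaussian_imbalanced` emulates the imbalanced, attributes ≫ patterns
regime (imbalance ratios up to ~4.3, thousands of columns) with two
unit-variance Gaussian clouds shifted by `mean_shift` on the informative
dimensions. `inject_missing` marks an exact rounded fraction of cells
missing uniformly at random, never blanking a whole column (a fully
missing column would make fold-wise mean imputation arbitrary).

What passing on these generators does **not** show: real expression data
have correlated attributes, batch structure, heavy tails and
class-conditional variance differences; none of these are modeled, so
synthetic-perfect scores are a correctness statement about the
implementation, not a performance claim about real data.

## Numerical choices and degenerate inputs

- All sorting is stable with ascending-index tie-breaks; the pipeline is
  deterministic end to end given data and seed.
- Strict inequalities everywhere a value can sit exactly on a threshold
  or boundary; such values are never errors and never class-1 votes.
- Zero tail norms in the angular transform define the angle as 0,
  keeping the transform total.
- `att`/`bound` out of range are clamped with a warning (relevant when DE
  proposes extremes); an absent class or an all-identical training matrix
  raises a degenerate-training error; a fold that loses a class reports
  the fold index.
- Attribute indices are 0-based in memory and 1-based in serialized
  models and reports; model JSON round-trips floats bit-exactly.
- `att` may alternatively be interpreted as a percentage of the attribute
  count (`att_is_percent`), rounded to the nearest integer and clamped to
  at least 1.

## Problem sizes

The test suite and examples run on desk-scale data chosen to exercise
every code path: shells of 30 × 53, random oracle-comparison datasets of
at most 12 × 6 (200 of them), DE budgets of 20 × 30 evaluations, and the
13 × 7 benchmark matrix. These sizes keep the full suite under a few
seconds while still covering the attributes ≫ patterns regime
(`gaussian_imbalanced` with 3 052 columns in one test).

## Known limitations

- Binary classification only; multi-class inputs are rejected at read
  time. Categorical attributes are not supported.
- The training error that DE minimizes is the *single best attribute's*
  1-D radial resubstitution error, not an aggregate over the progressive
  sets; datasets where no single attribute is radially informative give
  DE a flat fitness landscape.
- The Friedman p-value ignores tie correction (see above).
- The `global` LOOCV mode leaks the held-out patterns into tuning; use
  `per_fold` for honest estimates.
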