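# spheremml

A binary classifier for high-dimensional numeric data — the regime of
gene-expression phenotype tables, where attributes vastly outnumber
patterns and class sizes are imbalanced — built from a deliberately
minimal sequence of elementary operations, together with the evaluation
machinery to benchmark it: deterministic leave-one-out cross-validation,
balanced accuracy and F1, and Friedman/Holm multi-classifier comparison.

## The model

Given training data split by class into `Y1` and `Y2` (class codes 1
and 2), learning is:

1. **T-means thresholds.** For every attribute *j*, the threshold is the
   midpoint of the two class means, `T[j] = (mean(Y1[:,j]) + mean(Y2[:,j])) / 2`.
2. **Orientation error vectors.** `E1[j]` counts training values on the
   wrong side of `T[j]` assuming class 1 lies *below* the threshold;
   `E2[j]` assumes class 1 lies *above*. Values exactly on the threshold
   count in neither.
3. **Orientation flag.** `C1_IN = mean(E1) < mean(E2)`. When true,
   class 1 is modeled as lying *inside* the spherical decision
   boundaries; when false, outside.
4. **Attribute ranking.** Attributes are sorted by ascending `E1` (if
   `C1_IN`) or `E2` and the best `att` kept.
5. **Radial re-ranking.** Each kept attribute gets a 1-D radial boundary
   at the midpoint of the adjacent class extremes of |value|; attributes
   are re-ranked by the resubstitution error of that boundary. The
   training error is the minimum of these errors.
6. **Progressive spherical boundaries.** For k = 1…`bound`, the radial
   norm `r = sqrt(x_1² + … + x_k²)` of every training pattern over the
   first k re-ranked attributes is computed, and a boundary placed at
   the midpoint of the adjacent class extremes of those norms.

Classification projects a test pattern onto the learning attributes,
computes the progressive prefix norms, and lets each boundary vote:
with class 1 inside, a norm strictly below its boundary votes class 1
(strictly above, when class 1 is outside; equality votes class 2).
Class 1 is assigned when its votes reach at least `bound / 2`.

The two hyperparameters — `att` (candidate attributes kept) and `bound`
(progressive sets, i.e. votes) — are self-adjusted by integer-coded
**Differential Evolution** (`x_c + F·(x_a − x_b)` with binomial
crossover), minimizing the training error.

The underlying N-spherical coordinate view `(x_1,…,x_n) → (r, α_1,…,α_{n−1})`
is available in `spheremml.spherical`; the decision path uses only the
radial component.

## Worked example

`examples/train_and_classify.py` generates ball-vs-shell data (class 1
uniform in a ball of radius 1 over 3 informative attributes, class 2 on
a shell of radius 5–10, plus 50 noise attributes), learns a model and
classifies a held-out pattern:

```
orientation c1_in = True  (True: class 1 modeled inside)
learning attributes (0-based): [0, 1, 2]
spherical boundaries: [1.9637 2.8219 3.4564]
training error: 0

held-out pattern true class: 1
progressive norms: [0.0014 0.332  0.4506]
votes for class 1: 3 of 3
predicted class: 1
```

The learner recovered exactly the three informative attributes, oriented
class 1 inside, and the held-out pattern's prefix norms fall below all
three boundaries — three class-1 votes.

`examples/compare_classifiers.py` ranks seven classifiers over the
packaged 13-dataset balanced-accuracy benchmark:

```
mean ranks (lower is better):
  N-Spherical      1.5000   first in 10 dataset(s)
  Logistic         3.2308   first in 0 dataset(s)
  SMO              3.4615   first in 3 dataset(s)
  ...
Friedman chi-square = 30.7912, p = 2.78e-05

Holm post-hoc vs 'N-Spherical':
  MLP            z = 4.539206  p = 0.000006  threshold = 0.008333  -> significant
  ...
  Logistic       z = 2.042643  p = 0.041088  threshold = 0.050000  -> significant
```

All six comparisons against the spherical classifier survive the Holm
step-down at α = 0.05.

`examples/loocv_with_self_adjustment.py` runs leave-one-out evaluation
with Differential Evolution retuned inside every fold on an imbalanced
two-Gaussian dataset.

## Command line

The same functionality is available as a thin CLI:

```
spheremml simulate --kind shells --seed 7 --out shells.csv
spheremml train   --input shells.csv --positive-class 1 --att 5 --bound 3 --out model.json
spheremml predict --model model.json --input shells.csv --out predictions.csv
spheremml loocv   --input shells.csv --positive-class 1 --auto --seed 7 --out report.json
spheremml compare                      # packaged benchmark matrix
```

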