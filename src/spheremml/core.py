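"""Learning phase of the N-spherical minimalist classifier.

The learning phase is a fixed sequence of elementary operations:

1.  Split the training matrix by class (``Y1``, ``Y2``).
2.  Per attribute, compute the two class means and their midpoint — the
    *T-means* threshold.
3.  Per attribute, count threshold errors under each orientation
    hypothesis: ``e1`` assumes class 1 lies below the threshold, ``e2``
    assumes it lies above.
4.  The orientation flag ``c1_in = mean(e1) < mean(e2)`` decides whether
    class 1 is modeled as lying *inside* (True) or *outside* (False) the
    spherical decision boundaries.
5.  Rank attributes by the chosen error vector, keep the best ``att``.
6.  Score each kept attribute by the resubstitution error of a 1-D radial
    boundary (midpoint of the adjacent class extremes of |value|), and
    re-rank by that score; the training error is the minimum such score.
7.  Build ``bound`` progressive boundaries: for k = 1..bound, the radial
    norms of every training pattern over the first k re-ranked attributes
    are computed, and the boundary is the midpoint between the adjacent
    class extremes of those norms.

The assembled :class:`BoundaryModel` is everything the classification
phase needs: the orientation flag, the ordered learning attributes and
one radius per progressive set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import DegenerateTrainingError, LabeledDataset

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TMeansProfile:
    """Per-attribute class means, T-means thresholds and error vectors."""

    m1: np.ndarray
    m2: np.ndarray
    t_means: np.ndarray
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None


@dataclass(frozen=True)
class AttributeRanking:
    """Attribute indices (0-based) sorted by ascending error count."""

    ordered_indices: np.ndarray
    ordered_errors: np.ndarray


@dataclass
class BoundaryModel:
    """Output of the learning phase.

    ``learning_attributes`` are 0-based column indices into the training
    matrix, in re-ranked order; ``boundaries[k]`` is the radial decision
    boundary over the first ``k + 1`` of them.  Serialized form uses
    1-based indices, matching conventional reporting.
    """

    c1_in: bool
    learning_attributes: np.ndarray
    boundaries: np.ndarray
    att: int
    bound: int
    training_error: int
    class_names: dict[int, str] = field(default_factory=lambda: {1: "1", 2: "2"})
    per_set_errors: np.ndarray | None = None
    provenance: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "format_version": MODEL_FORMAT_VERSION,
            "c1_in": bool(self.c1_in),
            "learning_attributes": [int(a) + 1 for a in self.learning_attributes],
            "boundaries": [float(b) for b in self.boundaries],
            "att": int(self.att),
            "bound": int(self.bound),
            "training_error": int(self.training_error),
            "class_names": {str(k): v for k, v in self.class_names.items()},
        }
        if self.provenance is not None:
            d["provenance"] = self.provenance
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BoundaryModel":
        version = d.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"incompatible model format version {version!r}; "
                f"this build reads version {MODEL_FORMAT_VERSION}"
            )
        return cls(
            c1_in=bool(d["c1_in"]),
            learning_attributes=np.asarray(d["learning_attributes"], dtype=int) - 1,
            boundaries=np.asarray(d["boundaries"], dtype=float),
            att=int(d["att"]),
            bound=int(d["bound"]),
            training_error=int(d["training_error"]),
            class_names={int(k): v for k, v in d["class_names"].items()},
            provenance=d.get("provenance"),
        )


def split_by_class(data: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Partition the pattern matrix into class-1 and class-2 rows.

    Row order within each class is preserved.
    """
    y1 = data.values[data.labels == 1]
    y2 = data.values[data.labels == 2]
    if y1.shape[0] == 0 or y2.shape[0] == 0:
        raise DegenerateTrainingError(
            f"both classes required for training (n1={y1.shape[0]}, n2={y2.shape[0]})"
        )
    return y1, y2


def t_means(y1: np.ndarray, y2: np.ndarray) -> TMeansProfile:
    """Class column means and their per-attribute midpoints."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size == 0 or y2.size == 0:
        raise DegenerateTrainingError("empty class matrix")
    if y1.shape[1] != y2.shape[1]:
        raise ValueError(f"column count mismatch: {y1.shape[1]} vs {y2.shape[1]}")
    m1 = y1.mean(axis=0)
    m2 = y2.mean(axis=0)
    return TMeansProfile(m1=m1, m2=m2, t_means=(m1 + m2) / 2.0)


def error_vectors(
    y1: np.ndarray, y2: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold error counts under the two orientation hypotheses.

    ``e1[j]`` counts class-1 values strictly above plus class-2 values
    strictly below ``thresholds[j]`` (class 1 assumed below); ``e2[j]``
    is the mirror.  Values exactly equal to the threshold count in
    neither vector.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (y1.shape[1],):
        raise ValueError(
            f"threshold length {thresholds.shape} does not match {y1.shape[1]} attributes"
        )
    e1 = (y1 > thresholds).sum(axis=0) + (y2 < thresholds).sum(axis=0)
    e2 = (y1 < thresholds).sum(axis=0) + (y2 > thresholds).sum(axis=0)
    return e1.astype(int), e2.astype(int)


def orientation(e1: np.ndarray, e2: np.ndarray) -> bool:
    """Orientation criterion: True iff ``mean(e1) < mean(e2)`` strictly.

    True means class 1 is modeled as lying below the T-means thresholds
    and inside the spherical boundaries; ties yield False.
    """
    return bool(np.mean(e1) < np.mean(e2))


def rank_attributes(errors: np.ndarray, att: int) -> AttributeRanking:
    """Sort attribute indices by ascending error count, keep the best ``att``.

    Ties are broken by ascending attribute index (stable sort).  ``att``
    greater than the attribute count is clamped with a warning.
    """
    errors = np.asarray(errors)
    if att < 1:
        raise ValueError(f"att must be >= 1, got {att}")
    if att > errors.size:
        warnings.warn(
            f"att={att} exceeds {errors.size} attributes; clamping", stacklevel=2
        )
        att = errors.size
    order = np.argsort(errors, kind="stable")[:att]
    return AttributeRanking(ordered_indices=order, ordered_errors=errors[order])


def attribute_radius(r1: np.ndarray, r2: np.ndarray, c1_in: bool) -> float:
    """Radial decision boundary: midpoint of the adjacent class extremes.

    With class 1 inside (``c1_in``) the boundary sits between the largest
    class-1 radius and the smallest class-2 radius; otherwise between the
    smallest class-1 and the largest class-2 radius.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.size == 0 or r2.size == 0:
        raise DegenerateTrainingError("empty class radius vector")
    if c1_in:
        return float((r1.max() + r2.min()) / 2.0)
    return float((r1.min() + r2.max()) / 2.0)


def boundary_errors(r1: np.ndarray, r2: np.ndarray, boundary: float, c1_in: bool) -> int:
    """Resubstitution errors of a radial boundary.

    Radii strictly on the wrong side count as errors; radii exactly on
    the boundary are errors for neither class.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if c1_in:
        return int((r1 > boundary).sum() + (r2 < boundary).sum())
    return int((r1 < boundary).sum() + (r2 > boundary).sum())


def progressive_boundaries(
    y1_sel: np.ndarray, y2_sel: np.ndarray, bound: int, c1_in: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Boundaries of the nested progressive attribute sets.

    ``y1_sel`` / ``y2_sel`` hold the class matrices restricted to the
    re-ranked attributes, best first.  For each k = 1..bound the radial
    norm of every pattern over the first k columns is computed and a
    boundary placed at the midpoint of the adjacent class extremes;
    the per-set resubstitution error is recorded alongside.
    """
    y1_sel = np.asarray(y1_sel, dtype=float)
    y2_sel = np.asarray(y2_sel, dtype=float)
    if bound < 1:
        raise ValueError(f"bound must be >= 1, got {bound}")
    if bound > y1_sel.shape[1]:
        warnings.warn(
            f"bound={bound} exceeds {y1_sel.shape[1]} selected attributes; clamping",
            stacklevel=2,
        )
        bound = y1_sel.shape[1]
    # prefix radial norms: sqrt of cumulative sums of squares along attributes
    n1 = np.sqrt(np.cumsum(y1_sel[:, :bound] ** 2, axis=1))
    n2 = np.sqrt(np.cumsum(y2_sel[:, :bound] ** 2, axis=1))
    boundaries = np.empty(bound)
    per_set_errors = np.empty(bound, dtype=int)
    for k in range(bound):
        boundaries[k] = attribute_radius(n1[:, k], n2[:, k], c1_in)
        per_set_errors[k] = boundary_errors(n1[:, k], n2[:, k], boundaries[k], c1_in)
    return boundaries, per_set_errors


def learn(
    train: LabeledDataset,
    att: int,
    bound: int,
    att_is_percent: bool = False,
) -> BoundaryModel:
    """Run the full learning phase and assemble a :class:`BoundaryModel`.

    Parameters
    ----------
    train
        Complete (no missing values) two-class training data.
    att
        Number of candidate attributes retained after T-means error
        ranking (or a percentage of the attribute count when
        ``att_is_percent``).
    bound
        Number of progressive spherical boundaries, i.e. votes; must not
        exceed ``att`` (clamped with a warning otherwise).
    """
    train.require_complete()
    y1, y2 = split_by_class(train)
    if np.all(train.values == train.values[0]):
        raise DegenerateTrainingError("all training patterns are identical")

    L = train.n_attributes
    if att_is_percent:
        att = int(round(att * L / 100.0))
    att = max(1, min(att, L))
    if bound > att:
        warnings.warn(f"bound={bound} exceeds att={att}; clamping", stacklevel=2)
    bound = max(1, min(bound, att))

    profile = t_means(y1, y2)
    e1, e2 = error_vectors(y1, y2, profile.t_means)
    c1_in = orientation(e1, e2)
    ranking = rank_attributes(e1 if c1_in else e2, att)
    selected = ranking.ordered_indices

    # 1-D radial score per selected attribute: |value| is the radius
    r1 = np.abs(y1[:, selected])
    r2 = np.abs(y2[:, selected])
    att_errors = np.empty(att, dtype=int)
    for j in range(att):
        radius = attribute_radius(r1[:, j], r2[:, j], c1_in)
        att_errors[j] = boundary_errors(r1[:, j], r2[:, j], radius, c1_in)

    rerank = np.argsort(att_errors, kind="stable")
    learning_attributes = selected[rerank][:bound]
    training_error = int(att_errors.min())

    boundaries, per_set_errors = progressive_boundaries(
        y1[:, learning_attributes], y2[:, learning_attributes], bound, c1_in
    )
    return BoundaryModel(
        c1_in=c1_in,
        learning_attributes=learning_attributes,
        boundaries=boundaries,
        att=att,
        bound=bound,
        training_error=training_error,
        class_names=dict(train.class_names),
        per_set_errors=per_set_errors,
    )
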