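"""Seeded synthetic data generators.

These generators produce datasets with the statistical structure the
classifier assumes — a class separable from the other by a radial
frontier over a small set of informative attributes, buried among many
uninformative ones — so every module is testable without external data.

``radial_shells`` realizes the radial-separability premise directly: one
class occupies a ball around the origin, the other a shell well outside
it.  The shell class is placed in the positive orthant with every
informative coordinate magnitude at least ``outer_radius / sqrt(d)``,
which makes each informative attribute individually detectable by a
mean-midpoint threshold and individually separable by a 1-D radial
boundary.  A sign-symmetric shell would defeat any univariate mean-based
score (both classes would have per-attribute mean approximately zero), so
this one-sided construction is what "data matching the classifier's
assumptions" means here; see docs/methods.md.

``gaussian_imbalanced`` emulates the imbalanced microarray regime (two
Gaussian clouds, attributes >> patterns, imbalance ratios up to ~4.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset


@dataclass(frozen=True)
class ShellSpec:
    """Geometry of a ball-vs-shell synthetic dataset.

    ``n1`` / ``n2`` are the class-1 / class-2 sizes; ``inside_class``
    says which class occupies the inner ball.  Informative dimensions
    carry the geometry; ``noise_dims`` standard-normal columns (scaled by
    ``noise_scale``) are appended, identical in distribution for both
    classes.
    """

    n1: int = 15
    n2: int = 15
    informative_dims: int = 3
    noise_dims: int = 50
    inner_radius: float = 1.0
    outer_radius: float = 5.0
    inside_class: int = 1
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius < 0 or self.outer_radius <= self.inner_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")
        if self.inside_class not in (1, 2):
            raise ValueError("inside_class must be 1 or 2")
        if min(self.n1, self.n2, self.informative_dims) < 1 or self.noise_dims < 0:
            raise ValueError("invalid sizes")


def _uniform_ball(rng: np.random.Generator, n: int, d: int, radius: float) -> np.ndarray:
    """Uniform sampling in the d-ball: Gaussian direction, radius ~ U^(1/d)."""
    g = rng.standard_normal((n, d))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / d)
    return g * r[:, None]


def radial_shells(spec: ShellSpec) -> LabeledDataset:
    """Ball-vs-shell dataset; deterministic given ``spec.seed``.

    Inside-class patterns are uniform in the ball of ``inner_radius``
    over the informative dimensions.  Outside-class patterns have each
    informative coordinate drawn uniformly from
    ``[outer_radius / sqrt(d), 2 outer_radius / sqrt(d)]`` (positive
    orthant), so their radial norms lie exactly in
    ``[outer_radius, 2 outer_radius]``.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.informative_dims
    n_inside = spec.n1 if spec.inside_class == 1 else spec.n2
    n_outside = spec.n2 if spec.inside_class == 1 else spec.n1

    inside = _uniform_ball(rng, n_inside, d, spec.inner_radius)
    lo, hi = spec.outer_radius / np.sqrt(d), 2.0 * spec.outer_radius / np.sqrt(d)
    outside = rng.uniform(lo, hi, size=(n_outside, d))

    if spec.inside_class == 1:
        informative = np.vstack([inside, outside])
    else:
        informative = np.vstack([outside, inside])
    labels = np.concatenate([np.ones(spec.n1, dtype=int), np.full(spec.n2, 2, dtype=int)])

    noise = spec.noise_scale * rng.standard_normal((spec.n1 + spec.n2, spec.noise_dims))
    values = np.hstack([informative, noise])
    names = [f"inf_{j}" for j in range(d)] + [f"noise_{j}" for j in range(spec.noise_dims)]
    return LabeledDataset(values, labels, attribute_names=names)


def gaussian_imbalanced(
    n1: int,
    n2: int,
    dims: int,
    mean_shift: float,
    noise_dims: int = 0,
    seed: int = 0,
    scale: float = 1.0,
) -> LabeledDataset:
    """Two unit-variance Gaussian clouds separated by ``mean_shift`` on
    every informative dimension, plus optional shared noise columns.

    Supports the attributes >> patterns regime and arbitrary imbalance;
    the imbalance ratio is ``max(n1, n2) / min(n1, n2)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 patterns per class")
    rng = np.random.default_rng(seed)
    x1 = scale * rng.standard_normal((n1, dims))
    x2 = scale * rng.standard_normal((n2, dims)) + mean_shift
    values = np.vstack([x1, x2])
    if noise_dims:
        values = np.hstack(
            [values, scale * rng.standard_normal((n1 + n2, noise_dims))]
        )
    labels = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    names = [f"inf_{j}" for j in range(dims)] + [f"noise_{j}" for j in range(noise_dims)]
    return LabeledDataset(values, labels, attribute_names=names)


def imbalance_ratio(data: LabeledDataset) -> float:
    """Majority-class size divided by minority-class size."""
    return max(data.n1, data.n2) / min(data.n1, data.n2)


def inject_missing(data: LabeledDataset, fraction: float, seed: int = 0) -> LabeledDataset:
    """Mark ``round(fraction * N * L)`` cells missing (NaN), uniformly at
    random, never blanking an entire column."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    values = data.values.copy()
    n, L = values.shape
    n_missing = int(round(fraction * n * L))
    if n_missing == 0:
        return LabeledDataset(values, data.labels.copy(), data.attribute_names,
                              dict(data.class_names))
    rng = np.random.default_rng(seed)
    flat = rng.choice(n * L, size=n_missing, replace=False)
    mask = np.zeros(n * L, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n, L)
    # repair any fully-missing column by trading one of its cells for a
    # random still-present cell elsewhere
    for j in np.flatnonzero(mask.all(axis=0)):
        keep_row = int(rng.integers(n))
        mask[keep_row, j] = False
        free = np.argwhere(~mask)
        free = free[free[:, 1] != j]
        pick = free[int(rng.integers(len(free)))]
        mask[pick[0], pick[1]] = True
    values[mask] = np.nan
    return LabeledDataset(values, data.labels.copy(), data.attribute_names,
                          dict(data.class_names))
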