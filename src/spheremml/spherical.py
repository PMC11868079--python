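"""N-dimensional spherical coordinate transform and the radial norm.

A Cartesian point ``(x_1, ..., x_n)`` maps to ``(r, a_1, ..., a_{n-1})``
where ``r`` is the Euclidean norm and ``a_k = arccos(x_k / t_k)`` with
``t_k`` the norm of the tail ``(x_k, ..., x_n)``.  The classifier's
decision path uses only the radial component, computed on raw selected
Cartesian projections; the full angular transform is provided for
inspection.

Because the last angle is also defined through arccos, its range is
``[0, pi]`` and the sign of ``x_n`` is not recoverable from the angles;
the transform is therefore not invertible.  This matches the radial-only
use downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SphericalPoint:
    """Radius plus ``n - 1`` angles in ``[0, pi]`` radians."""

    radius: float
    angles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))


def _check_finite(x: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite component at index {bad[0]}")


def radial_norm(x) -> float:
    """Euclidean norm of a vector: sqrt of the sum of squared components.

    For a single component this is the absolute value — the radius of a
    1-D "sphere".
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("radial_norm of an empty vector is undefined")
    _check_finite(x)
    return float(np.linalg.norm(x))


def cartesian_to_nspherical(x) -> SphericalPoint:
    """Transform a Cartesian vector (length >= 2) to spherical coordinates.

    Angle ``k`` (0-based) is ``arccos(x_k / ||x_k..x_{n-1}||)``.  When a
    tail norm is exactly zero the arccos argument is 0/0; the angle is
    defined as 0, keeping the transform total (the angles are unused by
    the classifier decision path).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 components for a spherical transform")
    _check_finite(x)
    # tail_norms[k] = ||(x_k, ..., x_{n-1})||
    tail_norms = np.sqrt(np.cumsum(x[::-1] ** 2)[::-1])
    angles = np.zeros(x.size - 1)
    nz = tail_norms[:-1] > 0
    ratio = np.clip(x[:-1][nz] / tail_norms[:-1][nz], -1.0, 1.0)
    angles[nz] = np.arccos(ratio)
    return SphericalPoint(radius=float(tail_norms[0]), angles=angles)
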