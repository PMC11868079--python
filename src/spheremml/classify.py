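"""Classification phase: projection, progressive norms and voting.

A test pattern is projected onto the model's learning attributes.  For
each progressive set (the first k attributes, k = 1..bound) the radial
norm of the prefix is compared with the k-th spherical boundary.  With
class 1 modeled inside (``c1_in``), a norm strictly below the boundary
votes for class 1; with class 1 outside, a norm strictly above does.
Norms exactly on a boundary vote class 2 (strict inequalities).  Class 1
is assigned when its votes reach at least half of ``bound``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoundaryModel
from .dataset import ModelDataMismatchError


@dataclass(frozen=True)
class VoteTrace:
    """Audit record of one classification: projection, prefix norms, votes."""

    projections: np.ndarray
    norms: np.ndarray
    votes: np.ndarray  # boolean, True = vote for class 1
    predicted: int

    @property
    def votes_class1(self) -> int:
        return int(self.votes.sum())

    def to_dict(self) -> dict:
        return {
            "projections": [float(v) for v in self.projections],
            "norms": [float(v) for v in self.norms],
            "votes": [bool(v) for v in self.votes],
            "votes_class1": self.votes_class1,
            "predicted": int(self.predicted),
        }


def project(pattern, attributes) -> np.ndarray:
    """Restrict a pattern to the given attribute indices, in order."""
    pattern = np.asarray(pattern, dtype=float).ravel()
    attributes = np.asarray(attributes, dtype=int)
    if attributes.size and (attributes.min() < 0 or attributes.max() >= pattern.size):
        raise ModelDataMismatchError(
            f"model uses attribute index {attributes.max()} (0-based) but the "
            f"pattern has only {pattern.size} attributes"
        )
    return pattern[attributes]


def progressive_norms(projection) -> np.ndarray:
    """Radial norm of every prefix of the projection (non-decreasing)."""
    projection = np.asarray(projection, dtype=float).ravel()
    if projection.size == 0:
        raise ValueError("empty projection")
    return np.sqrt(np.cumsum(projection**2))


def vote_and_classify(norms, boundaries, c1_in: bool, projections=None) -> VoteTrace:
    """Compare prefix norms with boundaries and assign a class by voting.

    Vote k goes to class 1 iff ``norms[k] < boundaries[k]`` when class 1
    is inside, or ``norms[k] > boundaries[k]`` when outside; equality
    votes class 2.  Class 1 is predicted iff its vote count is at least
    half the number of boundaries.
    """
    norms = np.asarray(norms, dtype=float).ravel()
    boundaries = np.asarray(boundaries, dtype=float).ravel()
    if norms.shape != boundaries.shape or norms.size == 0:
        raise ModelDataMismatchError(
            f"{norms.size} norms vs {boundaries.size} boundaries"
        )
    votes = (norms < boundaries) if c1_in else (norms > boundaries)
    predicted = 1 if votes.sum() >= boundaries.size / 2.0 else 2
    if projections is None:
        projections = np.full(norms.shape, np.nan)
    return VoteTrace(
        projections=np.asarray(projections, dtype=float),
        norms=norms,
        votes=votes,
        predicted=predicted,
    )


def classify(model: BoundaryModel, pattern) -> tuple[int, VoteTrace]:
    """Classify one pattern with a learned model; fully deterministic."""
    proj = project(pattern, model.learning_attributes)
    norms = progressive_norms(proj)
    trace = vote_and_classify(norms, model.boundaries, model.c1_in, projections=proj)
    return trace.predicted, trace
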