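"""Labeled two-class dataset container and shared error types.

The classifier operates on a plain numeric pattern matrix (N patterns x L
attributes) with binary class codes {1, 2}.  Class 1 is the "positive"
class by convention; the original label strings are retained in
``class_names`` so predictions can be reported in the user's vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateTrainingError(ValueError):
    """Training data cannot support learning (a class is absent, or every
    pattern is identical)."""


class ModelDataMismatchError(ValueError):
    """A model refers to attributes a pattern does not have."""


class UndefinedMetricError(ValueError):
    """A performance metric is undefined for the given confusion counts."""


class UnsupportedLabelsError(ValueError):
    """Input labels are not a two-class problem."""


@dataclass
class LabeledDataset:
    """Numeric pattern matrix with binary class labels.

    Parameters
    ----------
    values
        ``(N, L)`` float array.  May contain NaN for missing entries prior
        to imputation (e.g. as produced by :func:`spheremml.synth.inject_missing`
        or read from a file with missing markers).
    labels
        ``(N,)`` integer array with entries in ``{1, 2}``.
    attribute_names
        Optional length-``L`` list of attribute identifiers.
    class_names
        Mapping from class code to the original label string.
    """

    values: np.ndarray
    labels: np.ndarray
    attribute_names: list[str] | None = None
    class_names: dict[int, str] = field(default_factory=lambda: {1: "1", 2: "2"})

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.values.shape[0]} patterns"
            )
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise UnsupportedLabelsError(f"class codes must be in {{1, 2}}, got {sorted(bad)}")
        if self.attribute_names is not None and len(self.attribute_names) != self.values.shape[1]:
            raise ValueError("attribute_names length does not match attribute count")

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 2))

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_complete(self) -> None:
        """Raise if any entry is missing or non-finite."""
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at pattern {bad[0]}, attribute {bad[1]}; "
                "impute or drop missing entries first"
            )

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Row subset (e.g. a cross-validation fold) sharing metadata."""
        return LabeledDataset(
            self.values[rows],
            self.labels[rows],
            attribute_names=self.attribute_names,
            class_names=dict(self.class_names),
        )
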