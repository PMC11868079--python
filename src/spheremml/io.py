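"""Readers and writers: tabular datasets (CSV, ARFF), models, predictions.

Label coding: the two distinct label strings are mapped to class codes
{1, 2}; class 1 is the user-designated positive class, or failing that
the lexicographically first label.  Missing feature markers ("", "NA",
"N/A", "?", "NaN") become NaN and are imputed fold-wise during
evaluation, never at read time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .core import BoundaryModel
from .dataset import LabeledDataset, UnsupportedLabelsError

MISSING_MARKERS = ("", "NA", "N/A", "?", "NaN", "nan")


def _code_labels(
    raw_labels: pd.Series, positive_class: str | None
) -> tuple[np.ndarray, dict[int, str]]:
    uniques = sorted(raw_labels.astype(str).unique())
    if len(uniques) != 2:
        raise UnsupportedLabelsError(
            f"expected exactly 2 classes, found {len(uniques)}: {uniques} "
            "(multi-class data is not supported)"
        )
    if positive_class is not None:
        if str(positive_class) not in uniques:
            raise ValueError(
                f"positive class {positive_class!r} not among labels {uniques}"
            )
        pos = str(positive_class)
    else:
        pos = uniques[0]
    neg = uniques[0] if uniques[1] == pos else uniques[1]
    labels = np.where(raw_labels.astype(str) == pos, 1, 2)
    return labels, {1: pos, 2: neg}


def _frame_to_dataset(
    df: pd.DataFrame, label_column: str | None, positive_class: str | None
) -> LabeledDataset:
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in {list(df.columns)}")
    labels, class_names = _code_labels(df[label_column], positive_class)
    features = df.drop(columns=[label_column])
    features = features.replace(list(MISSING_MARKERS), np.nan)
    values = np.empty(features.shape, dtype=float)
    for j, col in enumerate(features.columns):
        try:
            values[:, j] = pd.to_numeric(features[col], errors="raise")
        except (ValueError, TypeError):
            numeric = pd.to_numeric(features[col], errors="coerce")
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"non-numeric value {features[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            ) from None
    return LabeledDataset(
        values, labels, attribute_names=[str(c) for c in features.columns],
        class_names=class_names,
    )


def read_table(
    path,
    label_column: str | None = None,
    positive_class: str | None = None,
) -> LabeledDataset:
    """Read a CSV or ARFF dataset into a :class:`LabeledDataset`.

    The label column defaults to the last column.  The format is chosen
    by extension (``.arff`` vs anything else = CSV with a header row).
    """
    path = Path(path)
    if path.suffix.lower() == ".arff":
        data, meta = scipy_arff.loadarff(path)
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        df = pd.read_csv(path, keep_default_na=False)
    return _frame_to_dataset(df, label_column, positive_class)


def write_table(data: LabeledDataset, path) -> None:
    """Write a dataset as CSV with a header row and a trailing ``label``
    column holding the original label strings; NaN becomes an empty cell."""
    names = data.attribute_names or [f"a{j}" for j in range(data.n_attributes)]
    df = pd.DataFrame(data.values, columns=names)
    df["label"] = [data.class_names[int(c)] for c in data.labels]
    df.to_csv(path, index=False)


def write_model(model: BoundaryModel, path) -> None:
    """Serialize a model as JSON text; floats round-trip bit-exactly."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path) -> BoundaryModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    return BoundaryModel.from_dict(payload)


def write_predictions(
    path, pattern_ids, predictions, traces, model: BoundaryModel
) -> None:
    """CSV of per-pattern predictions with vote counts."""
    rows = {
        "pattern_id": list(pattern_ids),
        "predicted_class": [model.class_names[int(p)] for p in predictions],
        "votes_class1": [t.votes_class1 for t in traces],
        "bound": [model.bound] * len(traces),
    }
    pd.DataFrame(rows).to_csv(path, index=False)
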