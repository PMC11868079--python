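"""Independent brute-force re-implementation of the learning phase.

Plain Python loops, no numpy vectorization, no sorting shortcuts — used
only as an oracle to cross-check the packaged implementation on tiny
inputs.  Deliberately kept free of any spheremml imports.
"""

from __future__ import annotations

import math


def split(values, labels):
    y1 = [list(values[i]) for i in range(len(labels)) if labels[i] == 1]
    y2 = [list(values[i]) for i in range(len(labels)) if labels[i] == 2]
    return y1, y2


def column_mean(rows, j):
    return sum(r[j] for r in rows) / len(rows)


def tmeans_and_errors(y1, y2):
    L = len(y1[0])
    tm, e1, e2 = [], [], []
    for j in range(L):
        t = (column_mean(y1, j) + column_mean(y2, j)) / 2.0
        tm.append(t)
        above1 = sum(1 for r in y1 if r[j] > t)
        below1 = sum(1 for r in y1 if r[j] < t)
        above2 = sum(1 for r in y2 if r[j] > t)
        below2 = sum(1 for r in y2 if r[j] < t)
        e1.append(above1 + below2)
        e2.append(below1 + above2)
    return tm, e1, e2


def stable_rank(errors, att):
    """Selection of the att smallest error indices, ties by index, via
    repeated linear scans (no library sort)."""
    remaining = list(range(len(errors)))
    order = []
    while remaining and len(order) < att:
        best = remaining[0]
        for i in remaining[1:]:
            if errors[i] < errors[best]:
                best = i
        order.append(best)
        remaining.remove(best)
    return order


def radius_and_errors(vals1, vals2, c1_in):
    r1 = [abs(v) for v in vals1]
    r2 = [abs(v) for v in vals2]
    if c1_in:
        boundary = (max(r1) + min(r2)) / 2.0
        errs = sum(1 for v in r1 if v > boundary) + sum(1 for v in r2 if v < boundary)
    else:
        boundary = (min(r1) + max(r2)) / 2.0
        errs = sum(1 for v in r1 if v < boundary) + sum(1 for v in r2 if v > boundary)
    return boundary, errs


def prefix_norm(row, cols, k):
    return math.sqrt(sum(row[cols[i]] ** 2 for i in range(k)))


def learn_oracle(values, labels, att, bound):
    """Full learning phase by direct loops.

    Returns a dict with e1, e2, c1_in, ranking (selected attribute
    indices), att_errors, learning_attributes, boundaries,
    training_error.
    """
    y1, y2 = split(values, labels)
    _, e1, e2 = tmeans_and_errors(y1, y2)
    c1_in = (sum(e1) / len(e1)) < (sum(e2) / len(e2))
    errors = e1 if c1_in else e2
    att = min(att, len(errors))
    bound = min(bound, att)
    selected = stable_rank(errors, att)

    att_errors = []
    for j in selected:
        _, errs = radius_and_errors([r[j] for r in y1], [r[j] for r in y2], c1_in)
        att_errors.append(errs)
    rerank_local = stable_rank(att_errors, len(att_errors))
    learning = [selected[i] for i in rerank_local][:bound]
    training_error = min(att_errors)

    boundaries = []
    for k in range(1, bound + 1):
        n1 = [prefix_norm(r, learning, k) for r in y1]
        n2 = [prefix_norm(r, learning, k) for r in y2]
        if c1_in:
            boundaries.append((max(n1) + min(n2)) / 2.0)
        else:
            boundaries.append((min(n1) + max(n2)) / 2.0)

    return {
        "e1": e1,
        "e2": e2,
        "c1_in": c1_in,
        "ranking": selected,
        "att_errors": att_errors,
        "learning_attributes": learning,
        "boundaries": boundaries,
        "training_error": training_error,
    }
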