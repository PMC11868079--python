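import numpy as np
import pytest

import spheremml as sm


@pytest.fixture(scope="session")
def shells():
    """Well-separated ball-vs-shell data: 15+15 patterns, 3 informative
    and 50 noise dimensions, inner radius 1, outer radius 5."""
    return sm.radial_shells(sm.ShellSpec(seed=7))


@pytest.fixture(scope="session")
def shells_class2_inside():
    return sm.radial_shells(sm.ShellSpec(seed=7, inside_class=2))


@pytest.fixture(scope="session")
def benchmark():
    """Packaged 13 x 7 balanced-accuracy benchmark matrix."""
    return sm.reference_score_matrix()


@pytest.fixture()
def tiny():
    """A hand-checkable 6 x 3 dataset where attribute 1 separates the
    classes perfectly (class 1 below)."""
    values = np.array(
        [
            [5.0, 1.0, 0.3],
            [4.0, 2.0, 0.1],
            [6.0, 1.5, 0.2],
            [5.5, 8.0, 0.25],
            [4.5, 9.0, 0.15],
            [6.5, 10.0, 0.35],
        ]
    )
    labels = np.array([1, 1, 1, 2, 2, 2])
    return sm.LabeledDataset(values, labels)


def random_dataset(rng, max_patterns=12, max_attrs=6):
    """Small random two-class dataset for oracle comparisons."""
    n1 = int(rng.integers(2, max_patterns // 2 + 1))
    n2 = int(rng.integers(2, max_patterns // 2 + 1))
    L = int(rng.integers(1, max_attrs + 1))
    values = np.round(rng.normal(scale=3.0, size=(n1 + n2, L)), 3)
    labels = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    return sm.LabeledDataset(values, labels)
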