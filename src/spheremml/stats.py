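"""Friedman mean-rank test and Holm post-hoc classifier comparison.

Given a datasets x algorithms score matrix, each row is converted to
midranks (rank 1 = best, ties averaged), the Friedman chi-square
statistic is computed from the rank sums in its classic form (no
Iman-Davenport correction), and a step-down Holm procedure compares
every algorithm against a control (by default the best mean rank) using

    z_i = |R_control - R_i| / SE,    SE = sqrt(k (k+1) / (6 N)),

with two-sided normal p-values and thresholds alpha / (k - i) down the
table sorted by descending z.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ScoreMatrix:
    """Datasets x algorithms score table (e.g. balanced accuracies)."""

    scores: np.ndarray
    dataset_names: list[str]
    algorithm_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (datasets x algorithms)")
        n, k = self.scores.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 datasets and >= 2 algorithms, got {n} x {k}")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains missing or non-finite entries")
        if len(self.dataset_names) != n or len(self.algorithm_names) != k:
            raise ValueError("name vectors do not match the score matrix shape")

    @classmethod
    def from_csv(cls, path) -> "ScoreMatrix":
        """Read a CSV whose first column holds dataset names and whose
        header row holds algorithm names.  Lines starting with '#' are
        treated as comments."""
        df = pd.read_csv(path, comment="#", index_col=0)
        return cls(
            scores=df.to_numpy(dtype=float),
            dataset_names=[str(x) for x in df.index],
            algorithm_names=[str(x) for x in df.columns],
        )


@dataclass
class FriedmanResult:
    rank_matrix: np.ndarray
    mean_ranks: np.ndarray
    chi_square: float
    p_value: float
    algorithm_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_ranks": dict(zip(self.algorithm_names, map(float, self.mean_ranks))),
            "chi_square": self.chi_square,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class HolmComparison:
    algorithm: str
    z: float
    p: float
    threshold: float
    rejected: bool


@dataclass
class HolmResult:
    control: str
    alpha: float
    comparisons: list[HolmComparison]

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "alpha": self.alpha,
            "comparisons": [
                {
                    "algorithm": c.algorithm,
                    "z": c.z,
                    "p": c.p,
                    "threshold": c.threshold,
                    "rejected": c.rejected,
                }
                for c in self.comparisons
            ],
        }


def midranks(row, higher_is_better: bool = True) -> np.ndarray:
    """Within-row midranks: rank 1 for the best value, ties averaged.

    Every row of midranks sums to k (k + 1) / 2.
    """
    row = np.asarray(row, dtype=float)
    if not np.isfinite(row).all():
        raise ValueError("row contains non-finite entries")
    return sps.rankdata(-row if higher_is_better else row)


def friedman(scores: ScoreMatrix, higher_is_better: bool = True) -> FriedmanResult:
    """Friedman test over the score matrix.

    chi^2 = 12 / (N k (k+1)) * sum_j Rsum_j^2 - 3 N (k+1), with N
    datasets, k algorithms and Rsum_j the rank sum of algorithm j;
    p-value from chi-square with k - 1 degrees of freedom.
    """
    n, k = scores.scores.shape
    rank_matrix = np.vstack(
        [midranks(row, higher_is_better) for row in scores.scores]
    )
    rank_sums = rank_matrix.sum(axis=0)
    chi_square = float(12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1))
    p_value = float(sps.chi2.sf(chi_square, k - 1))
    return FriedmanResult(
        rank_matrix=rank_matrix,
        mean_ranks=rank_matrix.mean(axis=0),
        chi_square=chi_square,
        p_value=p_value,
        algorithm_names=list(scores.algorithm_names),
    )


def holm_posthoc(
    fr: FriedmanResult, alpha: float = 0.05, control: int | None = None
) -> HolmResult:
    """Step-down Holm comparison of every algorithm against a control.

    ``control`` is an algorithm index; None selects the best (lowest)
    mean rank.  Comparisons are sorted by descending z; the i-th sorted
    comparison uses threshold alpha / (k - i) with i = k-1 ... 1, and
    rejection stops at the first non-rejection.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = fr.mean_ranks.size
    n = fr.rank_matrix.shape[0]
    if control is None:
        control = int(np.argmin(fr.mean_ranks))
    if not 0 <= control < k:
        raise IndexError(f"control index {control} out of range for {k} algorithms")
    se = float(np.sqrt(k * (k + 1) / (6.0 * n)))
    others = [j for j in range(k) if j != control]
    zs = [abs(fr.mean_ranks[control] - fr.mean_ranks[j]) / se for j in others]
    order = sorted(range(len(others)), key=lambda i: -zs[i])
    comparisons: list[HolmComparison] = []
    still_rejecting = True
    for rank_pos, i in enumerate(order):
        z = zs[i]
        p = float(2.0 * sps.norm.sf(z))
        threshold = alpha / (k - 1 - rank_pos)
        rejected = still_rejecting and p <= threshold
        if not rejected:
            still_rejecting = False
        comparisons.append(
            HolmComparison(
                algorithm=fr.algorithm_names[others[i]] if fr.algorithm_names else str(others[i]),
                z=z,
                p=p,
                threshold=threshold,
                rejected=rejected,
            )
        )
    control_name = fr.algorithm_names[control] if fr.algorithm_names else str(control)
    return HolmResult(control=control_name, alpha=alpha, comparisons=comparisons)


def first_place_counts(scores: ScoreMatrix, higher_is_better: bool = True) -> np.ndarray:
    """Per algorithm, the number of datasets where it attains the row
    optimum; ties count for every tied algorithm."""
    s = scores.scores
    best = s.max(axis=1, keepdims=True) if higher_is_better else s.min(axis=1, keepdims=True)
    return (s == best).sum(axis=0).astype(int)


def reference_score_matrix() -> ScoreMatrix:
    """Packaged benchmark: balanced accuracies of seven classifiers on 13
    two-class biomedical datasets, transcribed from a published
    comparison study."""
    ref = importlib.resources.files("spheremml.data").joinpath(
        "benchmark_balanced_accuracy.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return ScoreMatrix.from_csv(path)
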