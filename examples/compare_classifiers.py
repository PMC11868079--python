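"""Rank seven classifiers across thirteen datasets with the Friedman test
and a Holm step-down post-hoc against the best-ranked one.

Uses the packaged benchmark of LOOCV balanced accuracies on 13 two-class
biomedical datasets.  Rank 1 is best within each dataset; ties share the
average of their positions.
"""

import spheremml as sm

benchmark = sm.reference_score_matrix()
fr = sm.friedman(benchmark)
firsts = sm.first_place_counts(benchmark)

print("mean ranks (lower is better):")
for name, rank, wins in sorted(zip(fr.algorithm_names, fr.mean_ranks, firsts),
                               key=lambda t: t[1]):
    print(f"  {name:<14s} {rank:8.4f}   first in {wins} dataset(s)")
print(f"Friedman chi-square = {fr.chi_square:.4f}, p = {fr.p_value:.3g}")

holm = sm.holm_posthoc(fr, alpha=0.05)
print(f"\nHolm post-hoc vs {holm.control!r}:")
for c in holm.comparisons:
    verdict = "significant" if c.rejected else "not significant"
    print(f"  {c.algorithm:<14s} z = {c.z:8.6f}  p = {c.p:.6f}  "
          f"threshold = {c.threshold:.6f}  -> {verdict}")
# A comparison is significant when its two-sided normal p-value falls at
# or below the step-down threshold alpha / (k - i).
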