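"""Cohort-level frequency comparisons.

Tests whether 6/20 patients with cancer-tissue somatic mutations is
significantly below an earlier series' 7/10, and compares heteroplasmy-
carrier frequencies across general population / patient normal tissues /
patient cancerous tissues using the bundled synthetic count table.
"""

from mitosoma.reference import _data_path
from mitosoma.stats import (
    heteroplasmy_frequencies,
    load_count_table,
    two_proportion_test,
)

r = two_proportion_test(6, 20, 7, 10, method="chi2",
                        labels=("this cohort", "earlier series"))
print(f"patient frequency {r.k1}/{r.n1} ({100*r.freq1:.0f}%) vs "
      f"{r.k2}/{r.n2} ({100*r.freq2:.0f}%): "
      f"chi2 = {r.statistic:.3f}, p = {r.p_value:.4f}")
for method in ("chi2_yates", "fisher"):
    alt = two_proportion_test(6, 20, 7, 10, method=method)
    print(f"  {method}: p = {alt.p_value:.4f}")

counts = load_count_table(_data_path("heteroplasmy_counts_synthetic.tsv"))
groups, comparisons, _ = heteroplasmy_frequencies(counts)
print("\nheteroplasmy-carrier frequencies (synthetic count table):")
for g in groups:
    print(f"  {g.group}: {g.carriers}/{g.total} ({100*g.frequency:.1f}%)")
for c in comparisons:
    print(f"  {c.group1} vs {c.group2}: p = {c.p_value:.3g}")
# Normal tissues of patients carry heteroplasmy far more often than the
# general population, and cancerous tissues more often still.
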