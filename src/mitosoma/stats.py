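"""Cohort-level frequency comparisons.

The unit of analysis is the individual: a patient either harbours (>= 1)
somatic/heteroplasmic mtDNA mutation in the relevant tissue class or does
not, so every comparison reduces to a 2x2 table of carriers vs totals.
Three methods are exposed side by side because small published cohorts are
analysed with different conventions: Pearson chi-square without continuity
correction (default), chi-square with Yates correction, and Fisher's exact
test (two-sided, point-probability summation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ProportionComparison:
    group1: str
    group2: str
    k1: int
    n1: int
    k2: int
    n2: int
    statistic: float
    p_value: float
    method: str

    @property
    def freq1(self) -> float:
        return self.k1 / self.n1

    @property
    def freq2(self) -> float:
        return self.k2 / self.n2


def two_proportion_test(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    method: str = "chi2",
    labels: tuple[str, str] = ("group1", "group2"),
) -> ProportionComparison:
    """Compare carrier proportions k1/n1 vs k2/n2 on a 2x2 table.

    ``chi2`` is the Pearson statistic without continuity correction with p
    from the chi-square distribution on 1 df; ``chi2_yates`` applies the
    continuity correction; ``fisher`` is the two-sided exact test.  Two
    all-zero success columns give p = 1 by convention.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise StatsError("zero total in a group")
        if not (0 <= k <= n):
            raise StatsError(f"invalid counts {k}/{n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if k1 == 0 and k2 == 0:
        return ProportionComparison(
            labels[0], labels[1], k1, n1, k2, n2, 0.0, 1.0, method
        )
    if k1 == n1 and k2 == n2:
        return ProportionComparison(
            labels[0], labels[1], k1, n1, k2, n2, 0.0, 1.0, method
        )
    if method == "chi2":
        res = sps.chi2_contingency(table, correction=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "chi2_yates":
        res = sps.chi2_contingency(table, correction=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "fisher":
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        statistic, p = float(odds), float(p)
    else:
        raise StatsError(f"unknown method {method!r}")
    return ProportionComparison(
        labels[0], labels[1], k1, n1, k2, n2, statistic, min(p, 1.0), method
    )


@dataclass
class GroupCounts:
    group: str
    carriers: int
    total: int

    @property
    def frequency(self) -> float:
        return self.carriers / self.total


HETEROPLASMY_GROUPS = ("general population", "patient normal tissues", "patient cancerous tissues")


def heteroplasmy_frequencies(
    counts: dict[str, tuple[int, int]],
    method: str = "chi2",
) -> tuple[list[GroupCounts], list[ProportionComparison], list[str]]:
    """Per-group heteroplasmy-carrier frequencies with pairwise tests.

    ``counts`` maps group name -> (carriers, total) for (a subset of) the
    groups general population / patient normal tissues / patient cancerous
    tissues.  Returns (group summaries, pairwise comparisons, warnings);
    missing groups yield partial output with a warning.
    """
    warnings = []
    groups = []
    for name in HETEROPLASMY_GROUPS:
        if name not in counts:
            warnings.append(f"missing group: {name}")
            continue
        carriers, total = counts[name]
        if total == 0:
            raise StatsError(f"group {name!r} has total 0")
        groups.append(GroupCounts(name, carriers, total))
    comparisons = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            comparisons.append(
                two_proportion_test(
                    a.carriers,
                    a.total,
                    b.carriers,
                    b.total,
                    method=method,
                    labels=(a.group, b.group),
                )
            )
    return groups, comparisons, warnings


def load_count_table(path) -> dict[str, tuple[int, int]]:
    """Read a group/carriers/total TSV into a counts mapping."""
    counts = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["group", "carriers", "total"]:
            raise StatsError(f"unexpected count-table header {header}")
        for line in fh:
            if not line.strip():
                continue
            group, carriers, total = line.rstrip("\n").split("\t")
            counts[group] = (int(carriers), int(total))
    return counts
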