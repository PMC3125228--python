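"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the package's codon-context machinery: effects are
derived by mutating the full genome string, re-extracting each gene, and
diffing whole translated proteins.
"""

from __future__ import annotations

import numpy as np

from mitosoma.reference import (
    GenomeAnnotation,
    ReferenceGenome,
    reverse_complement,
    translate_cds,
)


def brute_force_effect(
    position: int,
    alt: str,
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
) -> dict[str, str]:
    """Per-gene synonymous/nonsynonymous verdicts by whole-gene translation.

    Mutates the genome at ``position``, re-translates every overlapping
    protein gene from scratch, and compares protein strings.
    """
    mutated = (
        reference.sequence[: position - 1] + alt + reference.sequence[position:]
    )
    verdicts = {}
    for gene in annotation.gene_at(position):
        if gene.kind != "protein":
            continue
        ref_raw = reference.sequence[gene.start - 1 : gene.end]
        alt_raw = mutated[gene.start - 1 : gene.end]
        if gene.strand == "light":
            ref_raw = reverse_complement(ref_raw)
            alt_raw = reverse_complement(alt_raw)
        offset = (
            position - gene.start if gene.strand == "heavy" else gene.end - position
        )
        if offset // 3 >= len(gene) // 3:
            continue  # partial terminal codon
        ref_protein = translate_cds(ref_raw)
        alt_protein = translate_cds(alt_raw)
        verdicts[gene.name] = (
            "synonymous" if ref_protein == alt_protein else "nonsynonymous"
        )
    return verdicts


def chi2_statistic(k1: int, n1: int, k2: int, n2: int) -> float:
    """Closed-form Pearson chi-square for a 2x2 carriers/totals table."""
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    N = n1 + n2
    col1, col2 = a + c, b + d
    return N * (a * d - b * c) ** 2 / (n1 * n2 * col1 * col2)


def permutation_midp(
    k1: int, n1: int, k2: int, n2: int, ndraws: int, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(mid-p, MC standard error, observed point mass) of the conditional
    permutation null.

    Permuting group labels with margins fixed makes the first group's
    success count hypergeometric; the mid-p convention counts half the
    probability mass of the observed statistic, the standard continuity
    treatment when comparing a discrete null against an asymptotic p.
    The returned point mass is the null's discreteness resolution at the
    observed table — agreement with a continuous approximation cannot be
    expected below that granularity.
    """
    obs = chi2_statistic(k1, n1, k2, n2)
    succ = k1 + k2
    N = n1 + n2
    a = rng.hypergeometric(succ, N - succ, n1, size=ndraws)
    b = n1 - a
    c = succ - a
    d = n2 - c
    stat = N * (a * d - b * c) ** 2 / (n1 * n2 * succ * (N - succ))
    greater = np.mean(stat > obs + 1e-9)
    equal = float(np.mean(np.abs(stat - obs) <= 1e-9))
    p = float(greater + 0.5 * equal)
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / ndraws))
    return p, se, equal
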