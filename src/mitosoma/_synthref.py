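"""Deterministic builder for the bundled *synthetic* reference sequence.

The package ships a generated stand-in for the human mtDNA reference: it
reproduces the rCRS length (16,569 bp), the standard gene coordinates, open
reading frames with an ATG start and no internal stop codon under the
vertebrate mitochondrial code (including the light-strand ND6 frame), and
the two canonical poly-C tracts of the control region.  A small set of
positions discussed throughout the package documentation is anchored to a
fixed base so that their codon-level consequences are stable:

* third-codon-position sites 4532 (ND2, G) and 9275 (CO3, A) — transitions
  there are synonymous under the mitochondrial code;
* second-position sites 6718 (CO1, A), 15447 and 15276 (CYB, A), and the
  light-strand site 14288 (ND6, heavy-strand T) — any substitution there is
  nonsynonymous;
* first-position site 15332 (CYB, A);
* control-region sites 16093 (C) and 16365 (C);
* 5178 (ND2, C), used as a transversion-bearing haplogroup motif site.

Everything else is sampled from a seeded RNG with an mtDNA-like base
composition.  Regenerate the fixture with ``scripts/make_reference_fixture.py``.
"""

from __future__ import annotations

import itertools

import numpy as np

from .reference import (
    COMPLEMENT,
    MT_LENGTH,
    GenomeAnnotation,
    ReferenceGenome,
    VERTEBRATE_MITO_CODE,
    coding_sequence,
    translate_cds,
)

BASES = "ACGT"
#: approximate heavy-strand base composition of human mtDNA
BASE_WEIGHTS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}

ANCHORS = {
    4532: "G",
    9275: "A",
    6718: "A",
    14288: "T",
    15332: "A",
    15447: "A",
    15276: "A",
    16093: "C",
    16365: "C",
    5178: "C",
    9207: "A",  # CO3 initiator A (ATP6/CO3 single-base overlap)
}

_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_STOPS = {c for c, aa in VERTEBRATE_MITO_CODE.mapping.items() if aa == "*"}
_NON_STOP = [c for c in _ALL_CODONS if c not in _STOPS]


class _Infeasible(Exception):
    pass


def _codon_positions(gene, codon_index: int) -> list[int]:
    """Heavy-strand positions of codon slots 0..2, in coding order."""
    if gene.strand == "heavy":
        base = gene.start + 3 * codon_index
        return [base, base + 1, base + 2]
    base = gene.end - 3 * codon_index
    return [base, base - 1, base - 2]


def _fill_gene(gene, seq: list[str], locked: list[bool], rng) -> None:
    flip = gene.strand == "light"
    for ci in range(len(gene) // 3):
        positions = _codon_positions(gene, ci)
        constraints = {}
        for slot, pos in enumerate(positions):
            if locked[pos - 1]:
                b = seq[pos - 1]
                constraints[slot] = COMPLEMENT[b] if flip else b
        pool = ["ATG"] if ci == 0 else _NON_STOP
        candidates = [
            c for c in pool if all(c[s] == b for s, b in constraints.items())
        ]
        if not candidates:
            raise _Infeasible(f"{gene.name} codon {ci}")
        codon = candidates[int(rng.integers(len(candidates)))]
        for slot, pos in enumerate(positions):
            seq[pos - 1] = COMPLEMENT[codon[slot]] if flip else codon[slot]
            locked[pos - 1] = True
    # trailing incomplete-stop bases stay as background sequence


def _attempt(annotation: GenomeAnnotation, rng) -> str:
    probs = np.array([BASE_WEIGHTS[b] for b in BASES])
    seq = [BASES[i] for i in rng.choice(4, size=MT_LENGTH, p=probs)]
    locked = [False] * MT_LENGTH
    for pos, base in ANCHORS.items():
        seq[pos - 1] = base
        locked[pos - 1] = True
    # canonical control-region poly-C tracts (rCRS positions); the bases
    # flanking each tract are pinned non-C so the homopolymer runs stay
    # inside the exclusion windows, as in rCRS itself
    for pos in range(303, 316):
        seq[pos - 1] = "T" if pos == 310 else "C"
        locked[pos - 1] = True
    for pos in range(16184, 16194):
        seq[pos - 1] = "T" if pos == 16189 else "C"
        locked[pos - 1] = True
    for pos, base in ((302, "A"), (316, "G"), (16183, "A"), (16194, "A")):
        seq[pos - 1] = base
        locked[pos - 1] = True
    # pre-lock every initiator ATG so genes whose start lies inside an
    # overlapping upstream gene (ATP6 in ATP8, ND4 in ND4L) stay feasible
    for gene in annotation.protein_genes():
        flip = gene.strand == "light"
        for slot, pos in enumerate(_codon_positions(gene, 0)):
            base = COMPLEMENT["ATG"[slot]] if flip else "ATG"[slot]
            if locked[pos - 1] and seq[pos - 1] != base:
                raise _Infeasible(f"{gene.name} start conflicts with lock")
            seq[pos - 1] = base
            locked[pos - 1] = True
    for gene in annotation.protein_genes():
        _fill_gene(gene, seq, locked, rng)
    return "".join(seq)


def build_synthetic_reference(
    annotation: GenomeAnnotation, seed: int = 20110628
) -> ReferenceGenome:
    """Build the synthetic reference deterministically from ``seed``.

    Retries with consecutive sub-seeds until the overlapping-gene frames
    (ATP8/ATP6, ND4L/ND4, ATP6/CO3) admit stop-free codons in both frames.
    """
    for attempt in range(64):
        rng = np.random.default_rng(seed + attempt)
        try:
            sequence = _attempt(annotation, rng)
        except _Infeasible:
            continue
        ref = ReferenceGenome(sequence=sequence, name="rCRS-synthetic")
        _validate(ref, annotation)
        return ref
    raise RuntimeError("could not build a stop-free synthetic reference")


def _validate(ref: ReferenceGenome, annotation: GenomeAnnotation) -> None:
    for pos, base in ANCHORS.items():
        assert ref.base(pos) == base, (pos, base)
    for gene in annotation.protein_genes():
        protein = translate_cds(coding_sequence(gene, ref))
        assert protein[0] == "M", gene.name
        assert "*" not in protein, gene.name
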