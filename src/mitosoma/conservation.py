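"""Functional-effect and conservation annotation of somatic mutations.

Substitutions in protein genes are classified synonymous / nonsynonymous
under the vertebrate mitochondrial code (light-strand genes read on the
reverse complement); control-region and RNA-gene positions are non-coding,
indels in coding sequence are frameshifts.  Two conservation measures
contextualise each site:

* interspecies conservation — the fraction of species in a pre-aligned
  vertebrate panel whose base matches the human reference at the site;
* population conservation — how often any derived allele at the site
  occurs in a panel of complete genomes from the general population (a
  high frequency marks a mutational hotspot rather than a conserved site).
"""

from __future__ import annotations

from dataclasses import dataclass

from .compare import MtVariant
from .reference import (
    MT_LENGTH,
    GenomeAnnotation,
    ReferenceGenome,
    codon_context,
)
from .somatic import SomaticMutation


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneEffect:
    gene: str
    effect: str  # synonymous | nonsynonymous
    ref_aa: str
    alt_aa: str
    codon_index: int

    @property
    def change(self) -> str:
        return f"{self.ref_aa}{self.codon_index + 1}{self.alt_aa}"


@dataclass(frozen=True)
class EffectAnnotation:
    """Effect of one variant; per-gene detail for overlapping genes."""

    effect: str  # synonymous | nonsynonymous | non-coding | frameshift/indel
    subclass: str  # region label or amino-acid change summary
    per_gene: tuple[GeneEffect, ...] = ()


def classify_effect(
    variant: MtVariant,
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
) -> EffectAnnotation:
    """Synonymous/nonsynonymous classification of a substitution.

    For heteroplasmic variants the non-reference allele is evaluated.  At
    positions covered by overlapping protein genes the effect is computed
    per gene; the top-level label is nonsynonymous if any gene is affected.
    """
    region = annotation.classify_region(variant.position)
    if region != "protein":
        return EffectAnnotation(effect="non-coding", subclass=region)
    if not variant.is_substitution:
        return EffectAnnotation(effect="frameshift/indel", subclass="protein")
    derived = variant.derived_alleles
    if len(derived) != 1:
        # heteroplasmic pair of two non-reference bases: evaluate the
        # alphabetically first derived allele
        derived = derived[:1]
    alt = derived[0]
    genes = [
        f for f in annotation.gene_at(variant.position) if f.kind == "protein"
    ]
    effects = []
    for gene in genes:
        offset = (
            variant.position - gene.start
            if gene.strand == "heavy"
            else gene.end - variant.position
        )
        if offset // 3 >= len(gene) // 3:
            # partial terminal codon (stop completed by polyadenylation):
            # no codon-level effect is defined
            continue
        ref_ctx = codon_context(
            variant.position, None, reference, annotation, gene=gene.name
        )
        alt_ctx = codon_context(
            variant.position, alt, reference, annotation, gene=gene.name
        )
        effects.append(
            GeneEffect(
                gene=gene.name,
                effect=(
                    "synonymous"
                    if ref_ctx.amino_acid == alt_ctx.amino_acid
                    else "nonsynonymous"
                ),
                ref_aa=ref_ctx.amino_acid,
                alt_aa=alt_ctx.amino_acid,
                codon_index=ref_ctx.codon_index,
            )
        )
    if not effects:
        return EffectAnnotation(
            effect="incomplete-codon", subclass="partial terminal codon"
        )
    overall = (
        "nonsynonymous"
        if any(e.effect == "nonsynonymous" for e in effects)
        else "synonymous"
    )
    detail = ";".join(f"{e.gene}:{e.change}" for e in effects)
    return EffectAnnotation(
        effect=overall, subclass=detail, per_gene=tuple(effects)
    )


# ---------------------------------------------------------------------------
# Interspecies conservation


@dataclass
class SpeciesAlignment:
    """A pre-aligned vertebrate panel projected onto reference coordinates.

    Every record has length 16,569 (gaps as ``-``); the human record is the
    reference itself.
    """

    species: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.species.items():
            if len(seq) != MT_LENGTH:
                raise AnnotationError(
                    f"species {name}: aligned length {len(seq)} != {MT_LENGTH}"
                )

    def column(self, position: int) -> dict[str, str]:
        if not (1 <= position <= MT_LENGTH):
            raise AnnotationError(f"position {position} not covered")
        return {name: seq[position - 1] for name, seq in self.species.items()}


def interspecies_conservation(
    position: int,
    alignment: SpeciesAlignment,
    reference: ReferenceGenome,
) -> tuple[float, int]:
    """(conservation index, species count) at a reference position.

    The index is the fraction of non-human species whose aligned base
    equals the human reference base; gaps count as mismatches.
    """
    column = alignment.column(position)
    ref_base = reference.base(position)
    n = len(column)
    if n == 0:
        raise AnnotationError("empty species alignment")
    matches = sum(1 for b in column.values() if b.upper() == ref_base)
    return matches / n, n


# ---------------------------------------------------------------------------
# Population conservation


@dataclass
class PopulationPanel:
    """Variant profiles of published complete genomes from the general
    population; used as frequency denominators for hotspot assessment."""

    profiles: list[list[MtVariant]]

    @property
    def size(self) -> int:
        return len(self.profiles)


def population_conservation(
    variant: MtVariant | SomaticMutation, panel: PopulationPanel
) -> tuple[int, float]:
    """(hit count, frequency) of any derived allele at the variant's
    position across the panel."""
    if panel.size == 0:
        raise AnnotationError("empty population panel")
    position = variant.position
    hits = sum(
        1
        for profile in panel.profiles
        if any(v.position == position and v.is_substitution for v in profile)
    )
    return hits, hits / panel.size


# ---------------------------------------------------------------------------
# Cohort annotation helper


def annotate_mutations(
    mutations: list[SomaticMutation],
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
) -> None:
    """Fill region and effect fields of somatic mutations in place."""
    for m in mutations:
        m.region = annotation.classify_region(m.position)
        if m.representative is not None:
            eff = classify_effect(m.representative, reference, annotation)
            m.effect = eff.effect
            m.effect_detail = eff.subclass
        else:
            m.effect = "non-coding" if m.region != "protein" else None
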