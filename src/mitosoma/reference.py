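"""Reference model of the human mitochondrial genome.

Positions throughout the package are 1-based rCRS coordinates on a circular
16,569-bp molecule.  The control region (D-loop) wraps the origin and is
represented as two arcs, 16,024-16,569 and 1-576.  Protein genes are
translated with the vertebrate mitochondrial genetic code (NCBI table 2);
two genes (ND6 and several tRNAs) are encoded on the light strand and are
read on the reverse complement.

The bundled reference shipped with the package is a *synthetic* stand-in
for the revised Cambridge Reference Sequence: it has the rCRS length, the
standard rCRS gene coordinates, open reading frames free of internal stop
codons, and the canonical poly-C tracts around positions 310 and 16,189,
but its base composition is generated, not the deposited NC_012920
sequence.  Any single-record FASTA of length 16,569 can be substituted via
:func:`load_reference`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

MT_LENGTH = 16569
#: Control-region arcs in rCRS numbering (wraps the origin).
CONTROL_ARCS = ((16024, 16569), (1, 576))
#: Priority used to reduce overlapping features to a single region label.
REGION_PRIORITY = ("protein", "rRNA", "tRNA", "control", "non-coding")

_VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ReferenceError(ValueError):
    """Raised for malformed reference input."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome (1-based, inclusive)."""

    name: str
    start: int
    end: int
    strand: str  # "heavy" | "light"
    kind: str  # "protein" | "tRNA" | "rRNA" | "control" | "non-coding"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise ReferenceError(
                f"feature {self.name}: bad span {self.start}-{self.end}"
            )
        if self.strand not in ("heavy", "light"):
            raise ReferenceError(f"feature {self.name}: bad strand {self.strand}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop_bases(self) -> int:
        """Trailing bases beyond the last full codon (mt mRNAs may end in a
        partial stop completed by polyadenylation)."""
        return len(self) % 3 if self.kind == "protein" else 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeAnnotation:
    """Ordered feature list with total per-position lookup.

    Every position 1..16,569 maps to at least one feature; gaps between
    annotated genes are filled with synthetic "non-coding" spacer features
    so the lookup is total.  Overlapping genes (ATP8/ATP6, ND4L/ND4,
    boundary tRNAs) are all reported by :meth:`gene_at`; the single region
    label returned by :meth:`classify_region` resolves overlaps with the
    priority protein > rRNA > tRNA > control > non-coding.
    """

    features: list[GeneFeature]
    _by_position: list[list[GeneFeature]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self._fill_spacers()
        self._by_position = [[] for _ in range(MT_LENGTH + 1)]
        for feat in self.features:
            for pos in range(feat.start, feat.end + 1):
                self._by_position[pos].append(feat)

    def _fill_spacers(self) -> None:
        covered = [False] * (MT_LENGTH + 1)
        for feat in self.features:
            for pos in range(feat.start, feat.end + 1):
                covered[pos] = True
        pos = 1
        spacers = []
        while pos <= MT_LENGTH:
            if not covered[pos]:
                start = pos
                while pos <= MT_LENGTH and not covered[pos]:
                    pos += 1
                spacers.append(
                    GeneFeature(f"NC_{start}", start, pos - 1, "heavy", "non-coding")
                )
            else:
                pos += 1
        self.features = list(self.features) + spacers

    def _check_position(self, position: int) -> None:
        if not (1 <= position <= MT_LENGTH):
            raise ReferenceError(f"position {position} outside 1..{MT_LENGTH}")

    def gene_at(self, position: int) -> list[GeneFeature]:
        """All features overlapping ``position``, in annotation order."""
        self._check_position(position)
        return list(self._by_position[position])

    def classify_region(self, position: int) -> str:
        """Single region label for ``position`` (priority-resolved)."""
        feats = self.gene_at(position)
        kinds = {f.kind for f in feats}
        for kind in REGION_PRIORITY:
            if kind in kinds:
                return kind
        raise ReferenceError(f"position {position} has no feature")  # unreachable

    def protein_genes(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "protein"]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class ReferenceGenome:
    """A validated 16,569-bp mitochondrial reference sequence."""

    sequence: str
    name: str = "rCRS"

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ReferenceError(
                f"reference length != {MT_LENGTH} (got {len(self.sequence)})"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(f"non-ACGT characters in reference: {sorted(bad)}")

    def base(self, position: int) -> str:
        """Reference base at a 1-based position (circular indexing allowed)."""
        return self.sequence[(position - 1) % MT_LENGTH]


@dataclass(frozen=True)
class MitoCodonTable:
    """Vertebrate mitochondrial genetic code (NCBI translation table 2).

    AGA/AGG are stops, TGA is Trp, ATA is Met.  Exactly 64 entries; stops
    map to "*".
    """

    mapping: dict

    @classmethod
    def vertebrate(cls) -> "MitoCodonTable":
        table = _BioCodonTable.unambiguous_dna_by_id[2]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(mapping=mapping)


VERTEBRATE_MITO_CODE = MitoCodonTable.vertebrate()


def translate_codon(codon: str, table: MitoCodonTable = VERTEBRATE_MITO_CODE) -> str:
    """One-letter amino acid for ``codon`` ("*" for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _VALID_BASES:
        raise ReferenceError(f"invalid codon {codon!r}")
    return table.mapping[codon]


def translate_cds(seq: str, table: MitoCodonTable = VERTEBRATE_MITO_CODE) -> str:
    """Translate a coding-orientation nucleotide string codon by codon,
    ignoring a trailing incomplete codon."""
    return "".join(
        translate_codon(seq[i : i + 3], table) for i in range(0, len(seq) - 2, 3)
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CodonContext:
    """Reading-frame context of one genomic position inside a protein gene."""

    gene: str
    strand: str
    codon_index: int  # 0-based codon number within the CDS
    codon_offset: int  # 0-based slot of the queried position within the codon
    codon: str  # codon string in the gene's coding orientation
    amino_acid: str


def coding_sequence(gene: GeneFeature, reference: ReferenceGenome) -> str:
    """Gene sequence in coding orientation (light-strand genes are
    reverse-complemented)."""
    raw = reference.sequence[gene.start - 1 : gene.end]
    return reverse_complement(raw) if gene.strand == "light" else raw


def codon_context(
    position: int,
    base_override: str | None,
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
    gene: str | None = None,
) -> CodonContext:
    """Codon containing ``position``, optionally with a substituted base.

    ``base_override`` is given on the heavy strand (rCRS orientation); for
    light-strand genes it is complemented into the coding frame.  When the
    position falls in overlapping protein genes, ``gene`` selects which one
    (default: the first in annotation order).
    """
    feats = [f for f in annotation.gene_at(position) if f.kind == "protein"]
    if gene is not None:
        feats = [f for f in feats if f.name == gene]
    if not feats:
        raise ReferenceError(f"position {position} not protein-coding")
    feat = feats[0]
    if feat.strand == "heavy":
        offset = position - feat.start
    else:
        offset = feat.end - position
    codon_index, codon_offset = divmod(offset, 3)
    if codon_index >= (len(feat) // 3):
        raise ReferenceError(
            f"position {position} falls in the incomplete terminal codon of {feat.name}"
        )
    cds = coding_sequence(feat, reference)
    codon = list(cds[codon_index * 3 : codon_index * 3 + 3])
    if base_override is not None:
        base = base_override.upper()
        if base not in _VALID_BASES:
            raise ReferenceError(f"invalid override base {base_override!r}")
        codon[codon_offset] = base if feat.strand == "heavy" else COMPLEMENT[base]
    codon_str = "".join(codon)
    return CodonContext(
        gene=feat.name,
        strand=feat.strand,
        codon_index=codon_index,
        codon_offset=codon_offset,
        codon=codon_str,
        amino_acid=translate_codon(codon_str),
    )


# ---------------------------------------------------------------------------
# Loading


def load_reference(path: str | Path) -> ReferenceGenome:
    """Read a single-record FASTA and validate it as an mtDNA reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"reference FASTA must contain exactly one record (got {len(records)})"
        )
    rec = records[0]
    return ReferenceGenome(sequence=str(rec.seq).upper(), name=rec.id)


def load_annotation(path: str | Path) -> GenomeAnnotation:
    """Read the (gene, start, end, strand, kind) TSV annotation."""
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "start", "end", "strand", "kind"]:
            raise ReferenceError(f"unexpected annotation header {header}")
        for line in fh:
            if not line.strip():
                continue
            name, start, end, strand, kind = line.rstrip("\n").split("\t")
            feats.append(GeneFeature(name, int(start), int(end), strand, kind))
    return GenomeAnnotation(features=feats)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("mitosoma") / "data" / name)


def bundled_reference() -> ReferenceGenome:
    """The synthetic bundled reference (see module docstring)."""
    return load_reference(_data_path("rcrs_synthetic.fasta"))


def bundled_annotation() -> GenomeAnnotation:
    """The standard rCRS gene annotation shipped with the package."""
    return load_annotation(_data_path("rcrs_annotation.tsv"))
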