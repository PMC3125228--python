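"""Variant scoring of complete mtDNA genomes against the reference.

A sample genome (possibly carrying two-base IUPAC codes, the consensus
representation of heteroplasmy in direct Sanger sequencing) is globally
aligned to the 16,569-bp reference, every difference is scored as an
:class:`MtVariant`, and the classical poly-C-tract exclusion filters are
applied.  Variants are rendered in the compact field nomenclature:

* ``16189``        bare position — transition from the reference base
* ``16093A``       explicit base — transversion (suffix base is the allele)
* ``6718A/G``      heteroplasmy — both alleles, alphabetical
* ``249d``         single-position deletion
* ``315+C``        insertion after the anchor position (``315insC`` accepted)

``G4532A``-style ref-prefixed tokens are accepted on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib

from .reference import MT_LENGTH, ReferenceGenome

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: two-base IUPAC ambiguity codes <-> allele pairs (heteroplasmy encoding)
IUPAC_TO_PAIR = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
PAIR_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_PAIR.items()}
#: three- and four-base ambiguity codes: unresolvable by Sanger consensus
IUPAC_MULTI = frozenset("BDHVN")

#: homopolymer C-tract windows around 310 and 16189 whose length variation
#: is conventionally not scored
EXCLUSION_WINDOWS = ((303, 315), (16180, 16195))

SAMPLE_NAME_RE = re.compile(r"^(CP|CN|C)(\d+)$")


class VariantError(ValueError):
    """Malformed variant token or un-alignable input."""


@dataclass(frozen=True)
class MtVariant:
    """One scored difference from the reference.

    ``alleles`` holds the observed base(s) for substitutions (two entries,
    alphabetical, for a heteroplasmic site — one of them may equal the
    reference base), ``("-",)`` for a deletion, and the empty tuple for an
    insertion, whose bases live in ``inserted``.
    """

    position: int
    ref: str
    alleles: tuple[str, ...]
    kind: str  # transition | transversion | insertion | deletion
    heteroplasmic: bool = False
    inserted: str = ""
    unresolvable: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MT_LENGTH):
            raise VariantError(f"position {self.position} out of range")

    @property
    def is_substitution(self) -> bool:
        return self.kind in ("transition", "transversion")

    @property
    def derived_alleles(self) -> tuple[str, ...]:
        """Observed alleles other than the reference base."""
        return tuple(a for a in self.alleles if a != self.ref)

    @property
    def state(self) -> frozenset:
        """Allele state used for tissue comparison (set of observed bases)."""
        if self.kind == "insertion":
            return frozenset({f"+{self.inserted}"})
        return frozenset(self.alleles)

    def sort_key(self):
        return (self.position, self.kind, self.alleles, self.inserted)


def substitution_kind(ref: str, alt: str) -> str:
    """Transition/transversion classification of a single base change."""
    if ref == alt:
        raise VariantError(f"{ref}->{alt} is not a substitution")
    return "transition" if TRANSITION_PARTNER[ref] == alt else "transversion"


def make_substitution(
    position: int, ref: str, observed: tuple[str, ...]
) -> MtVariant:
    """Build a substitution variant from the observed allele set."""
    alleles = tuple(sorted(set(observed)))
    derived = [a for a in alleles if a != ref]
    if not derived:
        raise VariantError(f"no derived allele at {position}")
    kind = substitution_kind(ref, derived[0])
    return MtVariant(
        position=position,
        ref=ref,
        alleles=alleles,
        kind=kind,
        heteroplasmic=len(alleles) == 2,
    )


# ---------------------------------------------------------------------------
# Nomenclature

_VARIANT_RE = re.compile(
    r"^(?P<refbase>[ACGT])?(?P<pos>\d+)"
    r"(?P<rest>d|(?:\+|ins)[ACGT]+|[ACGT](?:/[ACGT])?|)$"
)


def parse_variant(text: str, reference: ReferenceGenome) -> MtVariant:
    """Parse one nomenclature token into an :class:`MtVariant`."""
    token = text.strip()
    m = _VARIANT_RE.match(token)
    if not m:
        raise VariantError(f"malformed variant token {token!r}")
    position = int(m.group("pos"))
    if not (1 <= position <= MT_LENGTH):
        raise VariantError(f"position out of range in token {token!r}")
    ref = reference.base(position)
    if m.group("refbase") and m.group("refbase") != ref:
        raise VariantError(
            f"token {token!r}: stated reference base {m.group('refbase')} "
            f"differs from actual {ref}"
        )
    rest = m.group("rest")
    if rest == "":
        return make_substitution(position, ref, (TRANSITION_PARTNER[ref],))
    if rest == "d":
        return MtVariant(position, ref, ("-",), "deletion")
    if rest.startswith("+") or rest.startswith("ins"):
        bases = rest[1:] if rest.startswith("+") else rest[3:]
        return MtVariant(position, ref, (), "insertion", inserted=bases)
    if "/" in rest:
        a, b = rest.split("/")
        if a == b:
            raise VariantError(f"token {token!r}: identical heteroplasmy alleles")
        return make_substitution(position, ref, (a, b))
    if rest == ref:
        raise VariantError(f"token {token!r}: allele equals reference base")
    return make_substitution(position, ref, (rest,))


def format_variant(variant: MtVariant) -> str:
    """Canonical nomenclature string for a variant."""
    pos = variant.position
    if variant.kind == "deletion":
        return f"{pos}d"
    if variant.kind == "insertion":
        return f"{pos}+{variant.inserted}"
    if variant.heteroplasmic:
        return f"{pos}{variant.alleles[0]}/{variant.alleles[1]}"
    (alt,) = variant.derived_alleles
    if variant.kind == "transition":
        return str(pos)
    return f"{pos}{alt}"


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class Alignment:
    """Per-position pairing of a sample genome against the reference.

    ``bases[p]`` (1-based dict access via :meth:`base_at`) is the sample
    base aligned to reference position ``p`` — an ACGT base, a two-base
    IUPAC code, another ambiguity code, or ``-`` for a deletion.
    ``insertions`` maps an anchor position to the sample bases inserted
    immediately after it.
    """

    bases: list[str]  # index 0 <-> position 1
    insertions: dict[int, str] = field(default_factory=dict)

    def base_at(self, position: int) -> str:
        return self.bases[position - 1]

    def identity(self, reference: ReferenceGenome) -> float:
        matches = 0
        for pos in range(1, MT_LENGTH + 1):
            b = self.bases[pos - 1]
            r = reference.base(pos)
            if b == r or (b in IUPAC_TO_PAIR and r in IUPAC_TO_PAIR[b]):
                matches += 1
        return matches / MT_LENGTH


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_to_reference(
    sample_sequence: str,
    reference: ReferenceGenome,
    min_identity: float = 0.95,
    length_slack: int = 50,
) -> Alignment:
    """Globally align a sample genome to the reference.

    Inputs are expected to be rCRS-registered complete genomes (length
    within ``length_slack`` of 16,569).  Uses optimal unit-cost global
    (Needleman-Wunsch) alignment; on near-identity genomes the per-position
    pairing is exact.  Raises if identity falls below ``min_identity``.
    """
    sample = sample_sequence.upper().replace("U", "T")
    if abs(len(sample) - MT_LENGTH) > length_slack:
        raise VariantError(
            f"sample length {len(sample)} outside {MT_LENGTH} +/- {length_slack}"
        )
    result = edlib.align(sample, reference.sequence, mode="NW", task="path")
    bases: list[str] = []
    insertions: dict[int, str] = {}
    qi = 0  # sample cursor
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        n = int(count)
        if op in ("=", "X", "M"):
            bases.extend(sample[qi : qi + n])
            qi += n
        elif op == "D":  # missing from sample
            bases.extend("-" * n)
        elif op == "I":  # extra sample bases, anchored after current position
            anchor = len(bases)  # 0 means before position 1; fold to 16569
            key = anchor if anchor >= 1 else MT_LENGTH
            insertions[key] = insertions.get(key, "") + sample[qi : qi + n]
            qi += n
    alignment = Alignment(bases=bases, insertions=insertions)
    ident = alignment.identity(reference)
    if ident < min_identity:
        raise VariantError(
            f"not a human mtDNA genome (identity {ident:.3f} < {min_identity})"
        )
    return alignment


def _right_shift_homopolymer(
    position: int, base: str, reference: ReferenceGenome
) -> int:
    """3'-most equivalent placement of a single-base indel in a homopolymer."""
    while position < MT_LENGTH and reference.base(position + 1) == base:
        position += 1
    return position


def call_variants(
    alignment: Alignment, reference: ReferenceGenome
) -> list[MtVariant]:
    """Score every difference in an alignment as an :class:`MtVariant`.

    Two-base IUPAC codes become heteroplasmic calls; three/four-base codes
    are flagged ``unresolvable``.  Single-base indels inside homopolymer
    runs are normalised to the 3'-most position.
    """
    variants: list[MtVariant] = []
    for pos in range(1, MT_LENGTH + 1):
        obs = alignment.base_at(pos)
        ref = reference.base(pos)
        if obs == ref:
            continue
        if obs == "-":
            shifted = _right_shift_homopolymer(pos, ref, reference)
            variants.append(
                MtVariant(shifted, reference.base(shifted), ("-",), "deletion")
            )
        elif obs in IUPAC_TO_PAIR:
            variants.append(make_substitution(pos, ref, IUPAC_TO_PAIR[obs]))
        elif obs in IUPAC_MULTI:
            variants.append(
                MtVariant(
                    pos, ref, (obs,), "transition",
                    heteroplasmic=True, unresolvable=True,
                )
            )
        else:
            variants.append(make_substitution(pos, ref, (obs,)))
    for anchor, inserted in alignment.insertions.items():
        pos = anchor
        if len(set(inserted)) == 1:
            pos = _right_shift_homopolymer(anchor, inserted[0], reference)
        variants.append(
            MtVariant(pos, reference.base(pos), (), "insertion", inserted=inserted)
        )
    return sorted(variants, key=MtVariant.sort_key)


def in_exclusion_window(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in EXCLUSION_WINDOWS)


def apply_exclusion_filters(
    variants: list[MtVariant],
) -> tuple[list[MtVariant], list[tuple[MtVariant, str]]]:
    """Split variants into (kept, excluded-with-reason).

    Length variation (insertions/deletions) inside the poly-C windows
    303-315 and 16,180-16,195 is excluded; substitutions there are kept.
    Unresolvable ambiguity calls are excluded from downstream counting.
    """
    kept: list[MtVariant] = []
    excluded: list[tuple[MtVariant, str]] = []
    for v in variants:
        if v.unresolvable:
            excluded.append((v, "unresolvable ambiguity code"))
        elif v.kind in ("insertion", "deletion") and in_exclusion_window(v.position):
            excluded.append((v, "C-tract length variation"))
        else:
            kept.append(v)
    return kept, excluded


# ---------------------------------------------------------------------------
# Applying variants to a sequence (used by the simulator and round trips)


def apply_variants(
    reference: ReferenceGenome, variants: list[MtVariant]
) -> str:
    """Rebuild a sample sequence from the reference and a variant list.

    Heteroplasmic substitutions are written as the two-base IUPAC code.
    """
    seq = list(reference.sequence)
    inserts: dict[int, str] = {}
    for v in variants:
        idx = v.position - 1
        if v.kind == "deletion":
            seq[idx] = ""
        elif v.kind == "insertion":
            inserts[v.position] = inserts.get(v.position, "") + v.inserted
        elif v.heteroplasmic:
            seq[idx] = PAIR_TO_IUPAC[frozenset(v.alleles)]
        else:
            (alt,) = v.derived_alleles
            seq[idx] = alt
    out = []
    for pos in range(1, MT_LENGTH + 1):
        out.append(seq[pos - 1])
        if pos in inserts:
            out.append(inserts[pos])
    return "".join(out)


# ---------------------------------------------------------------------------
# Sample profiles


@dataclass
class SampleProfile:
    """One tissue's complete variant profile."""

    sample_id: str
    patient_id: int
    tissue: str  # C | CP | CN
    variants: list[MtVariant]
    excluded: list[tuple[MtVariant, str]] = field(default_factory=list)
    haplogroup: str | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=MtVariant.sort_key)
        positions = [v.position for v in self.variants if v.is_substitution]
        if len(positions) != len(set(positions)):
            raise VariantError(
                f"{self.sample_id}: duplicate substitution positions"
            )

    def variant_at(self, position: int) -> MtVariant | None:
        for v in self.variants:
            if v.position == position and v.is_substitution:
                return v
        return None


def parse_sample_name(name: str) -> tuple[str, int]:
    """Split a 'C14'/'CP3'/'CN20'-style sample name into (tissue, patient)."""
    m = SAMPLE_NAME_RE.match(name)
    if not m:
        raise VariantError(f"sample name {name!r} does not match C/CP/CN convention")
    return m.group(1), int(m.group(2))


def profile_from_sequence(
    name: str, sequence: str, reference: ReferenceGenome
) -> SampleProfile:
    """Align, call, and filter one sample genome into a profile."""
    tissue, patient = parse_sample_name(name)
    alignment = align_to_reference(sequence, reference)
    raw = call_variants(alignment, reference)
    kept, excluded = apply_exclusion_filters(raw)
    return SampleProfile(
        sample_id=name,
        patient_id=patient,
        tissue=tissue,
        variants=kept,
        excluded=excluded,
    )
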