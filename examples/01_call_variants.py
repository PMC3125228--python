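"""Score variants in a single mtDNA genome against the reference.

Builds a genome carrying one homoplasmic transition, one heteroplasmic
site (as the IUPAC consensus code direct sequencing would report), and a
C-tract insertion, then aligns, calls, and filters.
"""

from mitosoma.compare import (
    align_to_reference,
    apply_exclusion_filters,
    apply_variants,
    call_variants,
    format_variant,
    parse_variant,
)
from mitosoma.reference import bundled_reference

reference = bundled_reference()

planted = [
    parse_variant("G4532A", reference),   # homoplasmic transition in ND2
    parse_variant("16093C/T", reference),  # heteroplasmic control-region site
    parse_variant("315+C", reference),     # C-tract length variation
]
genome = apply_variants(reference, planted)
# the +C insertion shifts downstream string indices by one
print(f"sample genome length: {len(genome)} bp "
      f"(consensus base at 16093: {genome[16093]})")

alignment = align_to_reference(genome, reference)
variants = call_variants(alignment, reference)
kept, excluded = apply_exclusion_filters(variants)

print("kept variants:    ", [format_variant(v) for v in kept])
print("excluded variants:", [(format_variant(v), why) for v, why in excluded])
# The bare token is a transition, 'C/T' marks heteroplasmy, and the 315+C
# insertion is excluded as conventional C-tract length variation.
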