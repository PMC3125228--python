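"""Haplogroup assignment and phylogeny-based quality control.

Assigns a clean profile, then shows how a tissue swap between haplogroups
and a chimeric (artificially recombined) profile are caught.
"""

from mitosoma.compare import SampleProfile, parse_variant
from mitosoma.haplogroups import (
    assign_haplogroup,
    bundled_tree,
    detect_artificial_recombination,
    detect_haplotype_shift,
)
from mitosoma.reference import bundled_reference

reference = bundled_reference()
tree = bundled_tree(reference)

d4_path = list(tree.nodes["D4"].expected_variants().values())
b4_path = list(tree.nodes["B4"].expected_variants().values())

profile = SampleProfile("C1", 1, "C", d4_path + [parse_variant("14288", reference)])
a = assign_haplogroup(profile, tree)
print(f"assignment: {a.haplogroup}  score={a.score:.3f}  "
      f"private={[v.position for v in a.private]}")
# Private variants (here 14288) are the candidates for somatic mutations.

assignments = {
    "C": assign_haplogroup(SampleProfile("C1", 1, "C", d4_path), tree),
    "CP": assign_haplogroup(SampleProfile("CP1", 1, "CP", b4_path), tree),
    "CN": assign_haplogroup(SampleProfile("CN1", 1, "CN", d4_path), tree),
}
verdict = detect_haplotype_shift(assignments)
print(f"haplotype-shift QC: {verdict.status}  {verdict.details}")
# A shift means sample mix-up, not somatic evolution: calling is refused.

chimera = SampleProfile("C2", 2, "C", d4_path + [m.variant for m in tree.nodes["B4"].motifs])
recomb = detect_artificial_recombination(chimera, tree)
print(f"artificial-recombination QC: {recomb.status}  {recomb.details}")
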