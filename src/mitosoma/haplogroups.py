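"""Haplogroup assignment and phylogeny-based quality control.

Each sample is placed on a rooted motif-labelled haplogroup tree: every
node carries the variants (relative to the reference) that define its
branch, and a sample is assigned to the node whose root-to-node motif path
best explains its variant profile.  The placement doubles as a data-quality
instrument:

* a *haplotype shift* — tissues of one patient landing on different
  haplogroups — signals sample mix-up, not somatic evolution;
* *artificial recombination* — private variants of a sample jointly
  reproducing the motif of a foreign haplogroup — signals a chimeric or
  contaminated sequence.

The bundled mini-phylotree is a deliberately small fixture of East-Asian
haplogroup names with synthetic motifs in this package's coordinate space;
it makes no claim of fidelity to any published phylogeny version.  Motif
tokens use the package nomenclature; a trailing ``!`` marks a back
mutation (the node expects the reference base again at that position).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .compare import MtVariant, SampleProfile, format_variant, parse_variant
from .reference import ReferenceGenome


class TreeError(ValueError):
    """Malformed haplogroup tree input."""


@dataclass(frozen=True)
class Motif:
    """One defining variant of a haplogroup branch.

    ``back=True`` encodes a back mutation: the branch reverts ``position``
    to the reference base, cancelling an ancestral motif variant.
    """

    token: str
    position: int
    back: bool = False
    variant: MtVariant | None = None


@dataclass
class HaplogroupNode:
    name: str
    motifs: list[Motif]
    depth: int
    parent: "HaplogroupNode | None" = None
    children: list["HaplogroupNode"] = field(default_factory=list)

    def path_from_root(self) -> list["HaplogroupNode"]:
        path = []
        node: HaplogroupNode | None = self
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def expected_variants(self) -> dict[int, MtVariant]:
        """Variant set implied by the root-to-node motif path, with back
        mutations cancelling ancestral gains."""
        expected: dict[int, MtVariant] = {}
        for node in self.path_from_root():
            for motif in node.motifs:
                if motif.back:
                    if motif.position not in expected:
                        raise TreeError(
                            f"{node.name}: back mutation {motif.token} cancels "
                            "nothing on its path"
                        )
                    del expected[motif.position]
                else:
                    expected[motif.position] = motif.variant
        return expected


@dataclass
class HaplogroupTree:
    root: HaplogroupNode
    nodes: dict[str, HaplogroupNode]

    def __iter__(self):
        return iter(self.nodes.values())

    def leaves(self) -> list[HaplogroupNode]:
        return [n for n in self.nodes.values() if not n.children]

    def motif_positions(self) -> set[int]:
        return {
            m.position for n in self.nodes.values() for m in n.motifs if not m.back
        }


def _parse_motif(token: str, reference: ReferenceGenome) -> Motif:
    token = token.strip()
    if token.endswith("!"):
        inner = parse_variant(token[:-1], reference)
        return Motif(token=token, position=inner.position, back=True)
    variant = parse_variant(token, reference)
    return Motif(token=token, position=variant.position, variant=variant)


def load_tree(path: str | Path, reference: ReferenceGenome) -> HaplogroupTree:
    """Read an indented-tabular tree file: ``depth<TAB>name<TAB>motifs``.

    Motifs are comma-separated nomenclature tokens; the root row has depth
    0 and usually no motifs.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (2, 3):
                raise TreeError(f"line {lineno}: expected 2-3 tab fields")
            depth = int(parts[0])
            name = parts[1].strip()
            tokens = [t for t in (parts[2].split(",") if len(parts) == 3 else []) if t]
            rows.append((lineno, depth, name, tokens))
    if not rows:
        raise TreeError("empty tree file")
    if rows[0][1] != 0:
        raise TreeError("first row must be the depth-0 root")
    nodes: dict[str, HaplogroupNode] = {}
    stack: list[HaplogroupNode] = []
    for lineno, depth, name, tokens in rows:
        if name in nodes:
            raise TreeError(f"line {lineno}: duplicate node name {name!r}")
        motifs = [_parse_motif(t, reference) for t in tokens]
        node = HaplogroupNode(name=name, motifs=motifs, depth=depth)
        if depth == 0:
            if stack:
                raise TreeError(f"line {lineno}: second depth-0 root {name!r}")
        else:
            if depth > len(stack):
                raise TreeError(f"line {lineno}: depth jump at {name!r}")
            parent = stack[depth - 1]
            node.parent = parent
            parent.children.append(node)
        del stack[depth:]
        stack.append(node)
        nodes[name] = node
    tree = HaplogroupTree(root=stack[0].path_from_root()[0], nodes=nodes)
    for node in tree:
        node.expected_variants()  # validates back-mutation consistency
    return tree


def bundled_tree(reference: ReferenceGenome) -> HaplogroupTree:
    """The bundled mini-phylotree fixture (>= 15 named haplogroups)."""
    path = Path(importlib.resources.files("mitosoma") / "data" / "mini_phylotree.tsv")
    return load_tree(path, reference)


# ---------------------------------------------------------------------------
# Assignment


@dataclass
class HaplogroupAssignment:
    haplogroup: str
    score: float
    matched: list[MtVariant]
    missing: list[MtVariant]
    private: list[MtVariant]


def _variant_matches(profile_variant: MtVariant, motif_variant: MtVariant) -> bool:
    if profile_variant.position != motif_variant.position:
        return False
    if motif_variant.kind == "deletion":
        return profile_variant.kind == "deletion"
    if motif_variant.kind == "insertion":
        return (
            profile_variant.kind == "insertion"
            and profile_variant.inserted == motif_variant.inserted
        )
    if not profile_variant.is_substitution:
        return False
    (alt,) = motif_variant.derived_alleles
    return alt in profile_variant.alleles


def _score_node(
    node: HaplogroupNode, variants: list[MtVariant]
) -> HaplogroupAssignment:
    expected = node.expected_variants()
    matched, missing = [], []
    matched_profile: set[int] = set()
    for motif_variant in expected.values():
        hit = next(
            (i for i, v in enumerate(variants) if _variant_matches(v, motif_variant)),
            None,
        )
        if hit is None:
            missing.append(motif_variant)
        else:
            matched.append(motif_variant)
            matched_profile.add(hit)
    private = [v for i, v in enumerate(variants) if i not in matched_profile]
    n_path, n_prof = len(expected), len(variants)
    t_path = len(matched) / n_path if n_path else 1.0
    t_prof = len(matched) / n_prof if n_prof else 1.0
    return HaplogroupAssignment(
        haplogroup=node.name,
        score=(t_path + t_prof) / 2.0,
        matched=matched,
        missing=missing,
        private=private,
    )


def assign_haplogroup(
    profile: SampleProfile, tree: HaplogroupTree
) -> HaplogroupAssignment:
    """Best-scoring haplogroup for a post-filter variant profile.

    Score is the Kulczynski mean of path-motif recall and profile-variant
    precision; ties go to the deeper node, then the lexicographically
    smaller name.  Private variants are the profile variants unexplained by
    the chosen path — downstream somatic candidates always live there.
    """
    if not tree.nodes:
        raise TreeError("empty tree")
    best: tuple | None = None
    for node in tree:
        a = _score_node(node, profile.variants)
        key = (a.score, node.depth, [-ord(c) for c in node.name])
        if best is None or key > best[0]:
            best = (key, a)
    assignment = best[1]
    profile.haplogroup = assignment.haplogroup
    return assignment


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QCVerdict:
    status: str  # consistent | shift | not-evaluable | flagged | clean
    details: list[str] = field(default_factory=list)


def detect_haplotype_shift(
    assignments: dict[str, HaplogroupAssignment]
) -> QCVerdict:
    """Within-patient haplogroup concordance check.

    A shift between tissues of one patient signals sample mix-up or
    contamination (mtDNA does not recombine; tissues share the germline).
    """
    if len(assignments) < 2:
        return QCVerdict("not-evaluable", ["fewer than two tissues assigned"])
    groups = {t: a.haplogroup for t, a in assignments.items()}
    names = set(groups.values())
    if len(names) == 1:
        return QCVerdict("consistent")
    majority = max(names, key=lambda n: list(groups.values()).count(n))
    discordant = [
        f"tissue {t}: {g} (cohort-member majority {majority})"
        for t, g in groups.items()
        if g != majority
    ]
    return QCVerdict("shift", discordant)


def detect_artificial_recombination(
    profile: SampleProfile,
    tree: HaplogroupTree,
    assignment: HaplogroupAssignment | None = None,
    min_variants: int = 3,
    min_motif_coverage: float = 0.6,
) -> QCVerdict:
    """Chimera / contamination check.

    Flags a profile whose private variants jointly reproduce >=
    ``min_variants`` variants covering >= ``min_motif_coverage`` of the
    defining motif of a haplogroup *outside* the assigned path.
    """
    if assignment is None:
        assignment = assign_haplogroup(profile, tree)
    path_names = {
        n.name for n in tree.nodes[assignment.haplogroup].path_from_root()
    }
    hits = []
    for node in tree:
        if node.name in path_names:
            continue
        own = [m.variant for m in node.motifs if not m.back]
        if not own:
            continue
        n_hit = sum(
            1
            for mv in own
            if any(_variant_matches(pv, mv) for pv in assignment.private)
        )
        if n_hit >= min_variants and n_hit / len(own) >= min_motif_coverage:
            hits.append(
                f"{n_hit}/{len(own)} of {node.name} motif present as private variants"
            )
    if hits:
        verdict = QCVerdict("flagged", hits)
        profile.qc_flags.append("artificial-recombination")
        return verdict
    return QCVerdict("clean")


# ---------------------------------------------------------------------------
# Export


def to_newick(tree: HaplogroupTree) -> str:
    """Newick rendering with motif tokens as node comments."""

    def render(node: HaplogroupNode) -> str:
        label = node.name
        if node.motifs:
            label += "[&motifs=" + "|".join(m.token for m in node.motifs) + "]"
        if node.children:
            return "(" + ",".join(render(c) for c in node.children) + ")" + label
        return label

    return render(tree.root) + ";"
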