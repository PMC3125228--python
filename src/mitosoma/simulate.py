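"""Synthetic tissue-trio cohorts with machine-readable ground truth.

The generator emulates the statistical design of a 20-patient whole-mtDNA
somatic screening study: haplogroup-structured germlines drawn on the
bundled motif tree, three tissues per patient (cancerous C, para-cancerous
CP, distant normal CN; one patient lacking CP under the defaults, so a
default cohort emits exactly 59 genomes), heteroplasmic somatic mutations
written into the carrying tissues as two-base IUPAC consensus codes, a
D-loop : protein-coding site ratio of about 7:11, and optional artifacts
(sample swaps between patients, phantom homoplasmic mutations) that the
phylogenetic quality control is designed to catch.

Direct Sanger sequencing only reports heteroplasmy when the minor allele
is abundant; the generator emulates that by emitting an IUPAC code only
when the event's minor fraction reaches ``detection_threshold`` (default
0.20) and marking weaker events undetectable in the truth table.

Every random choice flows from ``SimulationConfig.seed`` through
per-patient substreams, so identical configs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .compare import (
    EXCLUSION_WINDOWS,
    MtVariant,
    PAIR_TO_IUPAC,
    TRANSITION_PARTNER,
    apply_variants,
    format_variant,
    make_substitution,
)
from .conservation import PopulationPanel, SpeciesAlignment
from .haplogroups import HaplogroupTree
from .reference import CONTROL_ARCS, MT_LENGTH, GenomeAnnotation, ReferenceGenome

PATTERNS = ("cancer-only", "cancer+para", "normal-only", "all-normal-tissues")
#: tissues carrying the somatic allele under each pattern
PATTERN_TISSUES = {
    "cancer-only": ("C",),
    "cancer+para": ("C", "CP"),
    "normal-only": ("CN",),
    "all-normal-tissues": ("CP", "CN"),
}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the emulated design: 20 patients, 30% of patients with
    somatic mutation(s) in the cancerous tissue, one to three events per
    affected patient, all somatic events heteroplasmic with minor fraction
    uniform on 0.25-0.50 (a stand-in — per-event fractions are not
    observable from consensus sequences), consensus detection threshold
    0.20, D-loop : coding region weights 7 : 11, and exactly
    ``round(n_patients * missing_cp_probability)`` patients lacking the
    para-cancerous sample.
    """

    n_patients: int = 20
    affected_fraction: float = 0.30
    muts_per_affected: tuple[int, int] = (1, 3)
    minor_fraction_range: tuple[float, float] = (0.25, 0.50)
    detection_threshold: float = 0.20
    pattern_weights: dict = field(
        default_factory=lambda: {
            "cancer-only": 0.5,
            "cancer+para": 0.2,
            "normal-only": 0.15,
            "all-normal-tissues": 0.15,
        }
    )
    region_weights: dict = field(
        default_factory=lambda: {"control": 7.0, "coding": 11.0}
    )
    #: probability that an unaffected patient carries one normal-tissue-only
    #: somatic event (the design's normal tissues also mutate)
    normal_background_rate: float = 0.15
    germline_private_range: tuple[int, int] = (1, 3)
    missing_cp_probability: float = 1 / 20
    swap_rate: float = 0.0
    phantom_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in (
            "affected_fraction",
            "detection_threshold",
            "missing_cp_probability",
            "normal_background_rate",
            "swap_rate",
            "phantom_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if set(self.pattern_weights) - set(PATTERNS):
            raise ConfigError("unknown pattern in pattern_weights")
        if sum(self.pattern_weights.values()) <= 0:
            raise ConfigError("pattern_weights must have positive mass")
        if set(self.region_weights) != {"control", "coding"}:
            raise ConfigError("region_weights needs control and coding")
        lo, hi = self.muts_per_affected
        if not (1 <= lo <= hi):
            raise ConfigError("bad muts_per_affected range")
        lo, hi = self.minor_fraction_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("minor fraction range must lie in (0, 0.5]")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["muts_per_affected"] = list(d["muts_per_affected"])
        d["minor_fraction_range"] = list(d["minor_fraction_range"])
        d["germline_private_range"] = list(d["germline_private_range"])
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class SomaticTruth:
    patient_id: int
    position: int
    ref: str
    alt: str
    pattern: str
    tissues: tuple[str, ...]
    minor_fraction: float
    detectable: bool

    @property
    def token(self) -> str:
        alleles = sorted((self.ref, self.alt))
        return f"{self.position}{alleles[0]}/{alleles[1]}"


@dataclass
class PatientTruth:
    patient_id: int
    haplogroup: str
    germline_variants: list[str]
    somatic: list[SomaticTruth] = field(default_factory=list)
    artifacts: list[str] = field(default_factory=list)
    has_cp: bool = True


@dataclass
class TruthTable:
    patients: list[PatientTruth]

    def detectable_events(self) -> list[SomaticTruth]:
        return [e for p in self.patients for e in p.somatic if e.detectable]

    def to_json(self) -> str:
        return json.dumps(
            [dataclasses.asdict(p) for p in self.patients], indent=2
        )

    def to_tsv(self) -> str:
        lines = [
            "patient\tposition\ttoken\tpattern\ttissues\tminor_fraction\tdetectable"
        ]
        for p in self.patients:
            for e in p.somatic:
                lines.append(
                    f"{p.patient_id}\t{e.position}\t{e.token}\t{e.pattern}\t"
                    f"{','.join(e.tissues)}\t{e.minor_fraction:.3f}\t{e.detectable}"
                )
        return "\n".join(lines) + "\n"


@dataclass
class Cohort:
    """Simulated cohort: named genome records plus the generating truth."""

    records: list[tuple[str, str]]
    truth: TruthTable
    config: SimulationConfig

    def sequences(self) -> dict[str, str]:
        return dict(self.records)


# ---------------------------------------------------------------------------
# Position sampling


def _control_positions() -> list[int]:
    out = []
    for lo, hi in CONTROL_ARCS:
        out.extend(range(lo, hi + 1))
    return out


def _excluded(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in EXCLUSION_WINDOWS)


_POOL_CACHE: dict[tuple[int, str], list[int]] = {}


def candidate_positions(
    annotation: GenomeAnnotation, region: str, forbidden: set[int]
) -> list[int]:
    """Somatic-site candidates in a region class, minus exclusion windows,
    haplogroup motif sites, and already-used positions."""
    key = (id(annotation), region)
    if key not in _POOL_CACHE:
        if region == "control":
            pool = _control_positions()
        elif region == "coding":
            pool = [
                p
                for p in range(1, MT_LENGTH + 1)
                if annotation.classify_region(p) == "protein"
            ]
        else:
            raise ConfigError(f"unknown region class {region!r}")
        _POOL_CACHE[key] = [p for p in pool if not _excluded(p)]
    return [p for p in _POOL_CACHE[key] if p not in forbidden]


def _het_variant(position: int, reference: ReferenceGenome) -> tuple[MtVariant, str]:
    ref = reference.base(position)
    alt = TRANSITION_PARTNER[ref]
    return (
        make_substitution(position, ref, (ref, alt)),
        alt,
    )


# ---------------------------------------------------------------------------
# Germline


def simulate_germline(
    tree: HaplogroupTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    reference: ReferenceGenome,
) -> tuple[str, list[MtVariant], str]:
    """(haplogroup, germline variants, genome sequence) for one patient.

    The haplogroup is a uniform leaf of the tree; private variants are
    homoplasmic transitions at positions away from every motif site and
    the excluded windows.
    """
    leaves = tree.leaves()
    leaf = leaves[int(rng.integers(len(leaves)))]
    variants = list(leaf.expected_variants().values())
    forbidden = set(tree.motif_positions()) | {v.position for v in variants}
    lo, hi = config.germline_private_range
    n_private = int(rng.integers(lo, hi + 1))
    pool = [
        p
        for p in range(1, MT_LENGTH + 1)
        if p not in forbidden and not _excluded(p)
    ]
    for p in rng.choice(len(pool), size=n_private, replace=False):
        pos = pool[int(p)]
        ref = reference.base(pos)
        variants.append(make_substitution(pos, ref, (TRANSITION_PARTNER[ref],)))
        forbidden.add(pos)
    variants.sort(key=MtVariant.sort_key)
    return leaf.name, variants, apply_variants(reference, variants)


# ---------------------------------------------------------------------------
# Patients


def _weighted_choice(rng, weights: dict) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def simulate_patient(
    patient_id: int,
    germline: tuple[str, list[MtVariant], str],
    config: SimulationConfig,
    rng: np.random.Generator,
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
    tree: HaplogroupTree,
    has_cp: bool = True,
) -> tuple[dict[str, str], PatientTruth]:
    """Tissue sequences plus truth entries for one patient.

    Affected patients (Bernoulli ``affected_fraction``) draw 1-3 somatic
    events whose first pattern is forced to a cancer-tissue pattern;
    unaffected patients may still carry a single normal-tissue event with
    probability ``normal_background_rate``.  Every event is heteroplasmic
    and written into its carrying tissues as an IUPAC code when the minor
    fraction reaches the detection threshold.
    """
    haplogroup, germ_variants, germ_seq = germline
    truth = PatientTruth(
        patient_id=patient_id,
        haplogroup=haplogroup,
        germline_variants=[format_variant(v) for v in germ_variants],
        has_cp=has_cp,
    )
    tissues = ("C", "CP", "CN") if has_cp else ("C", "CN")
    events: list[SomaticTruth] = []
    affected = rng.random() < config.affected_fraction
    cancer_weights = {
        k: v
        for k, v in config.pattern_weights.items()
        if k in ("cancer-only", "cancer+para")
    }
    normal_weights = {
        k: v
        for k, v in config.pattern_weights.items()
        if k in ("normal-only", "all-normal-tissues")
    }
    if not has_cp:
        cancer_weights = {"cancer-only": 1.0}
        normal_weights = {"normal-only": 1.0}
    n_events = 0
    forced_cancer = False
    if affected:
        lo, hi = config.muts_per_affected
        n_events = int(rng.integers(lo, hi + 1))
        forced_cancer = True
    elif rng.random() < config.normal_background_rate:
        n_events = 1
    forbidden = (
        set(tree.motif_positions())
        | {v.position for v in germ_variants}
    )
    for i in range(n_events):
        if forced_cancer and i == 0:
            pattern = _weighted_choice(rng, cancer_weights)
        elif not forced_cancer:
            pattern = _weighted_choice(rng, normal_weights)
        else:
            weights = dict(config.pattern_weights)
            if not has_cp:
                weights = {
                    "cancer-only": weights.get("cancer-only", 0)
                    + weights.get("cancer+para", 0),
                    "normal-only": weights.get("normal-only", 0)
                    + weights.get("all-normal-tissues", 0),
                }
            pattern = _weighted_choice(rng, weights)
        region = _weighted_choice(rng, config.region_weights)
        pool = candidate_positions(annotation, region, forbidden)
        pos = pool[int(rng.integers(len(pool)))]
        forbidden.add(pos)
        ref = reference.base(pos)
        alt = TRANSITION_PARTNER[ref]
        lo_f, hi_f = config.minor_fraction_range
        frac = float(rng.uniform(lo_f, hi_f))
        events.append(
            SomaticTruth(
                patient_id=patient_id,
                position=pos,
                ref=ref,
                alt=alt,
                pattern=pattern,
                tissues=PATTERN_TISSUES[pattern],
                minor_fraction=frac,
                detectable=frac >= config.detection_threshold,
            )
        )
    truth.somatic = events
    sequences = {}
    for tissue in tissues:
        seq = list(germ_seq)
        for e in events:
            if tissue in e.tissues and e.detectable:
                # germline background is the reference base at somatic sites
                code = PAIR_TO_IUPAC[frozenset((e.ref, e.alt))]
                seq[e.position - 1] = code
        sequences[tissue] = "".join(seq)
    return sequences, truth


# ---------------------------------------------------------------------------
# Cohort assembly and artifacts


def simulate_cohort(
    config: SimulationConfig,
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
    tree: HaplogroupTree,
) -> Cohort:
    """Simulate a full cohort deterministically from ``config.seed``."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    n_missing = int(round(config.n_patients * config.missing_cp_probability))
    setup_rng = np.random.default_rng(master.spawn(1)[0])
    missing_cp = set(
        int(i) + 1
        for i in setup_rng.choice(
            config.n_patients, size=n_missing, replace=False
        )
    )
    records: list[tuple[str, str]] = []
    patients: list[PatientTruth] = []
    for pid in range(1, config.n_patients + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, pid])
        )
        germline = simulate_germline(tree, config, rng, reference)
        has_cp = pid not in missing_cp
        sequences, truth = simulate_patient(
            pid, germline, config, rng, reference, annotation, tree, has_cp
        )
        patients.append(truth)
        for tissue in ("C", "CP", "CN"):
            if tissue in sequences:
                records.append((f"{tissue}{pid}", sequences[tissue]))
    cohort = Cohort(records=records, truth=TruthTable(patients), config=config)
    art_rng = np.random.default_rng(master.spawn(2)[1])
    inject_artifacts(cohort, config, art_rng)
    return cohort


def inject_artifacts(
    cohort: Cohort, config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Apply configured artifact processes to a cohort, logging each one.

    A sample swap exchanges one tissue's genome between two patients of
    different haplogroups (so haplotype-shift QC must later flag both); a
    phantom mutation adds a spurious homoplasmic variant to one tissue.
    """
    log: list[str] = []
    if config.swap_rate > 0 and rng.random() < config.swap_rate:
        log.extend(inject_swap(cohort, rng))
    if config.phantom_rate > 0 and rng.random() < config.phantom_rate:
        log.extend(inject_phantom(cohort, rng))
    return log


def inject_swap(cohort: Cohort, rng: np.random.Generator) -> list[str]:
    """Swap one tissue's sequence between two patients of different
    haplogroups; errors if the cohort has fewer than two haplogroups."""
    by_hap: dict[str, list[PatientTruth]] = {}
    for p in cohort.truth.patients:
        by_hap.setdefault(p.haplogroup, []).append(p)
    if len(by_hap) < 2:
        raise ConfigError("sample swap needs >= 2 distinct haplogroups")
    haps = sorted(by_hap)
    h1, h2 = (
        haps[i]
        for i in rng.choice(len(haps), size=2, replace=False)
    )
    p1 = by_hap[h1][int(rng.integers(len(by_hap[h1])))]
    p2 = by_hap[h2][int(rng.integers(len(by_hap[h2])))]
    shared = [
        t
        for t in ("C", "CP", "CN")
        if (t == "CP" and p1.has_cp and p2.has_cp) or t != "CP"
    ]
    tissue = shared[int(rng.integers(len(shared)))]
    names = {name: i for i, (name, _) in enumerate(cohort.records)}
    i1, i2 = names[f"{tissue}{p1.patient_id}"], names[f"{tissue}{p2.patient_id}"]
    (n1, s1), (n2, s2) = cohort.records[i1], cohort.records[i2]
    cohort.records[i1], cohort.records[i2] = (n1, s2), (n2, s1)
    msg = f"swap:{tissue}:{p1.patient_id}<->{p2.patient_id}"
    p1.artifacts.append(msg)
    p2.artifacts.append(msg)
    return [msg]


def inject_phantom(cohort: Cohort, rng: np.random.Generator) -> list[str]:
    """Add a spurious homoplasmic transition to a single tissue."""
    p = cohort.truth.patients[int(rng.integers(len(cohort.truth.patients)))]
    tissues = ("C", "CP", "CN") if p.has_cp else ("C", "CN")
    tissue = tissues[int(rng.integers(len(tissues)))]
    name = f"{tissue}{p.patient_id}"
    idx = next(i for i, (n, _) in enumerate(cohort.records) if n == name)
    seq = list(cohort.records[idx][1])
    while True:
        pos = int(rng.integers(1, MT_LENGTH + 1))
        if _excluded(pos) or seq[pos - 1] not in TRANSITION_PARTNER:
            continue
        break
    seq[pos - 1] = TRANSITION_PARTNER[seq[pos - 1]]
    cohort.records[idx] = (name, "".join(seq))
    msg = f"phantom:{name}:{pos}"
    p.artifacts.append(msg)
    return [msg]


# ---------------------------------------------------------------------------
# Output


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, truth TSV/JSON, and a YAML config echo; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "cohort.fasta",
        "truth_tsv": outdir / "truth.tsv",
        "truth_json": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in cohort.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["truth_tsv"].write_text(cohort.truth.to_tsv())
    paths["truth_json"].write_text(cohort.truth.to_json())
    paths["config"].write_text(cohort.config.to_yaml())
    return paths


# ---------------------------------------------------------------------------
# Conservation fixtures (generated, not bundled: a 13-species alignment
# would dwarf the package's text fixtures)


def simulate_species_alignment(
    reference: ReferenceGenome,
    n_species: int = 13,
    divergence: tuple[float, float] = (0.10, 0.30),
    conserved_positions: tuple[int, ...] = (),
    seed: int = 13,
) -> SpeciesAlignment:
    """Synthetic pre-aligned vertebrate panel in reference coordinates.

    Each species is the reference with a per-species fraction of positions
    substituted; ``conserved_positions`` are never touched, emulating
    deeply conserved sites.
    """
    rng = np.random.default_rng(seed)
    keep = set(conserved_positions)
    species = {}
    for i in range(n_species):
        rate = float(rng.uniform(*divergence))
        seq = list(reference.sequence)
        n_mut = int(rate * MT_LENGTH)
        for idx in rng.choice(MT_LENGTH, size=n_mut, replace=False):
            pos = int(idx) + 1
            if pos in keep:
                continue
            choices = [b for b in "ACGT" if b != seq[idx]]
            seq[idx] = choices[int(rng.integers(3))]
        species[f"species_{i + 1:02d}"] = "".join(seq)
    return SpeciesAlignment(species=species)


def simulate_population_panel(
    reference: ReferenceGenome,
    tree: HaplogroupTree,
    n_genomes: int = 100,
    hotspots: dict[int, float] | None = None,
    private_range: tuple[int, int] = (0, 4),
    seed: int = 3635,
) -> PopulationPanel:
    """Synthetic panel of population variant profiles.

    Each genome is a random haplogroup's motif path plus a few private
    transitions; ``hotspots`` maps positions to per-genome carrier
    probabilities (e.g. the 16093 hotspot of the control region).
    """
    rng = np.random.default_rng(seed)
    hotspots = hotspots or {}
    leaves = tree.leaves()
    profiles = []
    for _ in range(n_genomes):
        leaf = leaves[int(rng.integers(len(leaves)))]
        variants = list(leaf.expected_variants().values())
        used = {v.position for v in variants} | set(tree.motif_positions())
        lo, hi = private_range
        for _ in range(int(rng.integers(lo, hi + 1))):
            while True:
                pos = int(rng.integers(1, MT_LENGTH + 1))
                if pos not in used and not _excluded(pos):
                    break
            used.add(pos)
            ref = reference.base(pos)
            variants.append(
                make_substitution(pos, ref, (TRANSITION_PARTNER[ref],))
            )
        for pos, prob in hotspots.items():
            if pos not in used and rng.random() < prob:
                ref = reference.base(pos)
                variants.append(
                    make_substitution(pos, ref, (TRANSITION_PARTNER[ref],))
                )
                used.add(pos)
        profiles.append(sorted(variants, key=MtVariant.sort_key))
    return PopulationPanel(profiles=profiles)


# ---------------------------------------------------------------------------
# Deterministic reconstruction of the emulated study design


#: (patient, position, pattern) of the 18 heteroplasmic somatic events in
#: the reconstructed 20-patient design: 7 control-region + 11 coding events,
#: two of them synonymous (4532, 9275), nine nonsynonymous events over the
#: five sites 6718/14288/15332/15447/15276 with 14288 recurring in three
#: patients of different haplogroups, six patients with cancer-tissue
#: mutations, and normal-tissue mutations confined to patients 1, 3, 8, 14
#: and 20.
STUDY_EVENTS = (
    (1, 6718, "cancer+para"),
    (1, 15332, "cancer-only"),
    (1, 14288, "normal-only"),
    (2, 4532, "cancer-only"),
    (2, 146, "cancer-only"),
    (3, 16365, "cancer+para"),
    (3, 15447, "cancer-only"),
    (3, 16311, "cancer-only"),
    (6, 15332, "cancer-only"),
    (6, 16129, "cancer-only"),
    (8, 14288, "all-normal-tissues"),
    (10, 15447, "cancer-only"),
    (10, 195, "cancer-only"),
    (14, 16093, "all-normal-tissues"),
    (14, 14288, "normal-only"),
    (17, 15276, "cancer-only"),
    (17, 16223, "cancer-only"),
    (20, 9275, "normal-only"),
)

#: patient -> haplogroup leaf; the three 14288 carriers (1, 8, 14) sit on
#: three different haplogroups
STUDY_HAPLOGROUPS = {
    1: "D4b", 2: "D5", 3: "G", 4: "M7b", 5: "C", 6: "Z", 7: "A", 8: "B4",
    9: "Y", 10: "B5", 11: "F1", 12: "R9", 13: "D4a1", 14: "F1", 15: "D5",
    16: "G", 17: "M7b", 18: "C", 19: "A", 20: "B4",
}

STUDY_MISSING_CP = (19,)


def study_profile_cohort(
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
    tree: HaplogroupTree,
    seed: int = 2011,
) -> Cohort:
    """Deterministic 20-patient, 59-genome cohort with the emulated study's
    headline profile hard-wired into the truth (the sequences themselves
    still have to be re-profiled by the pipeline to recover it)."""
    rng = np.random.default_rng(seed)
    reserved = {pos for _, pos, _ in STUDY_EVENTS} | tree.motif_positions()
    events_by_patient: dict[int, list[tuple[int, str]]] = {}
    for pid, pos, pattern in STUDY_EVENTS:
        events_by_patient.setdefault(pid, []).append((pos, pattern))
    records = []
    patients = []
    for pid in range(1, 21):
        leaf = tree.nodes[STUDY_HAPLOGROUPS[pid]]
        variants = list(leaf.expected_variants().values())
        used = set(reserved) | {v.position for v in variants}
        for _ in range(int(rng.integers(1, 4))):
            while True:
                pos = int(rng.integers(1, MT_LENGTH + 1))
                if pos not in used and not _excluded(pos):
                    break
            used.add(pos)
            ref = reference.base(pos)
            variants.append(
                make_substitution(pos, ref, (TRANSITION_PARTNER[ref],))
            )
        variants.sort(key=MtVariant.sort_key)
        germ_seq = apply_variants(reference, variants)
        has_cp = pid not in STUDY_MISSING_CP
        truth = PatientTruth(
            patient_id=pid,
            haplogroup=leaf.name,
            germline_variants=[format_variant(v) for v in variants],
            has_cp=has_cp,
        )
        for pos, pattern in events_by_patient.get(pid, []):
            ref_base = reference.base(pos)
            truth.somatic.append(
                SomaticTruth(
                    patient_id=pid,
                    position=pos,
                    ref=ref_base,
                    alt=TRANSITION_PARTNER[ref_base],
                    pattern=pattern,
                    tissues=PATTERN_TISSUES[pattern],
                    minor_fraction=0.35,
                    detectable=True,
                )
            )
        for tissue in ("C", "CP", "CN"):
            if tissue == "CP" and not has_cp:
                continue
            seq = list(germ_seq)
            for e in truth.somatic:
                if tissue in e.tissues:
                    seq[e.position - 1] = PAIR_TO_IUPAC[
                        frozenset((e.ref, e.alt))
                    ]
            records.append((f"{tissue}{pid}", "".join(seq)))
        patients.append(truth)
    config = SimulationConfig(seed=seed)
    return Cohort(records=records, truth=TruthTable(patients), config=config)
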