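"""Within-patient tissue comparison: pinpointing somatic mtDNA mutations.

A somatic mutation is any position where the allele states of a patient's
tissues disagree — including homoplasmic <-> heteroplasmic shifts where the
homoplasmic base is one of the heteroplasmic pair.  Inherited (germline)
variants are shared identically by all tissues of a patient and never
appear here.

The germline state at a discordant site is taken to be the modal
*homoplasmic* state among the tissues (heteroplasmy is treated as the
derived condition; ties are broken toward the distant-normal tissue, then
the para-cancerous tissue, then the reference base).  The tissues that
deviate from the germline define the tissue-distribution pattern:

====================  ==========================================
pattern               deviating tissues
====================  ==========================================
cancer-only           C
cancer+para           C and CP (possible invasion of the
                      para-cancerous tissue by cancer cells)
normal-only           CN
all-normal-tissues    CP and CN
para-only             CP
other                 anything else
====================  ==========================================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .compare import MtVariant, SampleProfile, format_variant
from .haplogroups import QCVerdict

TISSUES = ("C", "CP", "CN")

#: patterns in which the cancerous tissue itself deviates from germline
CANCER_TISSUE_PATTERNS = frozenset({"cancer-only", "cancer+para"})


class TrioError(ValueError):
    """Invalid trio construction or QC-refused comparison."""


@dataclass
class PatientTrio:
    """Profiles of one patient's tissues (CP may be missing)."""

    patient_id: int
    profiles: dict[str, SampleProfile]

    def __post_init__(self) -> None:
        unknown = set(self.profiles) - set(TISSUES)
        if unknown:
            raise TrioError(f"patient {self.patient_id}: unknown tissues {unknown}")
        if len(self.profiles) < 2:
            raise TrioError(
                f"patient {self.patient_id}: need at least two tissues"
            )
        for t, p in self.profiles.items():
            if p.patient_id != self.patient_id:
                raise TrioError(
                    f"profile {p.sample_id} does not belong to patient "
                    f"{self.patient_id}"
                )
            if p.tissue != t:
                raise TrioError(f"profile {p.sample_id} filed under tissue {t}")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(t for t in TISSUES if t in self.profiles)


@dataclass(frozen=True)
class TissueState:
    """Allele state of one tissue at one position.

    ``tokens`` is the tuple of nomenclature strings of the variants the
    tissue carries there; the empty tuple is the reference (germline-
    background) state.
    """

    tokens: tuple[str, ...]
    heteroplasmic: bool

    @property
    def is_reference(self) -> bool:
        return not self.tokens


REFERENCE_STATE = TissueState(tokens=(), heteroplasmic=False)


@dataclass
class SomaticMutation:
    """One tissue-discordant site of one patient."""

    patient_id: int
    position: int
    states: dict[str, TissueState]
    pattern: str
    deviating: tuple[str, ...]
    heteroplasmic: bool
    invasion_flag: bool = False
    region: str | None = None
    effect: str | None = None
    effect_detail: str | None = None
    representative: MtVariant | None = None


def _states_at(
    trio: PatientTrio, position: int
) -> dict[str, TissueState]:
    states = {}
    for tissue in trio.tissues:
        here = [
            v for v in trio.profiles[tissue].variants if v.position == position
        ]
        states[tissue] = TissueState(
            tokens=tuple(sorted(format_variant(v) for v in here)),
            heteroplasmic=any(v.heteroplasmic for v in here),
        )
    return states


def _germline_state(states: dict[str, TissueState]) -> TissueState:
    pool = [s for s in states.values() if not s.heteroplasmic]
    if not pool:  # all tissues heteroplasmic: fall back to modal state
        pool = list(states.values())
    counts = Counter(pool)
    top = max(counts.values())
    modal = [s for s, c in counts.items() if c == top]
    if len(modal) == 1:
        return modal[0]
    for tissue in ("CN", "CP", "C"):
        s = states.get(tissue)
        if s in modal:
            return s
    return REFERENCE_STATE


def classify_pattern(
    states: dict[str, TissueState],
) -> tuple[str, TissueState, tuple[str, ...]]:
    """Tissue-distribution pattern of one discordant site.

    Returns ``(pattern, germline_state, deviating_tissues)``.  Total and
    deterministic over every 2- and 3-tissue state combination.
    """
    if len(states) < 2:
        raise TrioError("pattern needs at least two tissues")
    germline = _germline_state(states)
    deviating = tuple(
        t for t in TISSUES if t in states and states[t] != germline
    )
    label = {
        ("C",): "cancer-only",
        ("C", "CP"): "cancer+para",
        ("CN",): "normal-only",
        ("CP", "CN"): "all-normal-tissues",
        ("CP",): "para-only",
    }.get(deviating, "other")
    return label, germline, deviating


def compare_trio(
    trio: PatientTrio, qc: QCVerdict | None = None
) -> list[SomaticMutation]:
    """Position-by-position comparison of a patient's tissues.

    Emits one :class:`SomaticMutation` per position where the allele states
    are not all identical.  Refuses to call when a haplotype-shift QC
    verdict is supplied (discordant haplogroups mean a probable sample
    mix-up, so within-patient differences are not somatic).
    """
    if qc is not None and qc.status == "shift":
        raise TrioError(
            f"patient {trio.patient_id}: possible sample mix-up; "
            "somatic calling refused"
        )
    positions = sorted(
        {
            v.position
            for t in trio.tissues
            for v in trio.profiles[t].variants
        }
    )
    mutations = []
    for pos in positions:
        states = _states_at(trio, pos)
        if len(set(states.values())) == 1:
            continue  # germline: identical in all tissues
        pattern, germline, deviating = classify_pattern(states)
        het = any(states[t].heteroplasmic for t in deviating)
        rep = None
        for t in deviating:
            rep = trio.profiles[t].variant_at(pos) or rep
        mutations.append(
            SomaticMutation(
                patient_id=trio.patient_id,
                position=pos,
                states=states,
                pattern=pattern,
                deviating=deviating,
                heteroplasmic=het,
                invasion_flag=(pattern == "cancer+para"),
                representative=rep,
            )
        )
    return mutations


def find_recurrent(
    cohort: dict[int, list[SomaticMutation]],
    haplogroups: dict[int, str] | None = None,
) -> dict[int, tuple[int, int]]:
    """Positions mutated in >= 2 patients -> (patient count, distinct
    haplogroup count of the carriers)."""
    if not cohort:
        raise TrioError("empty cohort")
    carriers: dict[int, set[int]] = {}
    for patient, muts in cohort.items():
        for m in muts:
            carriers.setdefault(m.position, set()).add(patient)
    out = {}
    for pos, patients in carriers.items():
        if len(patients) < 2:
            continue
        if haplogroups:
            n_hap = len({haplogroups.get(p) for p in patients})
        else:
            n_hap = 0
        out[pos] = (len(patients), n_hap)
    return out


@dataclass
class CohortSummary:
    """Headline tabulation of a cohort's somatic-mutation profile."""

    n_patients: int
    patients_with_cancer_tissue: int
    total_mutations: int
    region_counts: dict[str, int] = field(default_factory=dict)
    effect_counts: dict[str, int] = field(default_factory=dict)
    nonsynonymous_sites: int = 0
    synonymous_sites: int = 0
    heteroplasmic_fraction: float = 0.0
    pattern_counts: dict[str, int] = field(default_factory=dict)
    recurrent: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def cancer_tissue_frequency(self) -> float:
        return (
            self.patients_with_cancer_tissue / self.n_patients
            if self.n_patients
            else 0.0
        )


def summarize_cohort(
    cohort: dict[int, list[SomaticMutation]],
    n_patients: int | None = None,
    haplogroups: dict[int, str] | None = None,
) -> CohortSummary:
    """Pure tabulation of per-patient somatic mutation lists.

    A patient "carries a cancer-tissue somatic mutation" when at least one
    of their mutations has the cancerous tissue deviating from germline
    (patterns cancer-only or cancer+para).  Effect counts are reported both
    as events and as distinct sites because recurrent sites make the two
    differ.
    """
    n = n_patients if n_patients is not None else len(cohort)
    all_muts = [m for muts in cohort.values() for m in muts]
    with_cancer = sum(
        1
        for muts in cohort.values()
        if any(m.pattern in CANCER_TISSUE_PATTERNS for m in muts)
    )
    region_counts: Counter = Counter(m.region for m in all_muts if m.region)
    effect_counts: Counter = Counter(m.effect for m in all_muts if m.effect)
    nonsyn_sites = len(
        {m.position for m in all_muts if m.effect == "nonsynonymous"}
    )
    syn_sites = len({m.position for m in all_muts if m.effect == "synonymous"})
    het_frac = (
        sum(1 for m in all_muts if m.heteroplasmic) / len(all_muts)
        if all_muts
        else 0.0
    )
    recurrent = find_recurrent(cohort, haplogroups) if cohort else {}
    return CohortSummary(
        n_patients=n,
        patients_with_cancer_tissue=with_cancer,
        total_mutations=len(all_muts),
        region_counts=dict(region_counts),
        effect_counts=dict(effect_counts),
        nonsynonymous_sites=nonsyn_sites,
        synonymous_sites=syn_sites,
        heteroplasmic_fraction=het_frac,
        pattern_counts=dict(Counter(m.pattern for m in all_muts)),
        recurrent=recurrent,
    )
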