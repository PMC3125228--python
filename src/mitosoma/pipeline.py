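"""End-to-end orchestration: align -> call -> filter -> assign -> QC ->
compare -> annotate -> tabulate.

The entry point is :func:`profile_cohort`, which takes named genome
records (sample names following the C/CP/CN-suffix convention), runs every
stage, and returns a :class:`CohortResult` holding per-sample profiles,
per-patient QC verdicts, annotated somatic mutations, and the cohort
summary.  QC failures are reported per patient without aborting the rest
of the cohort; unparseable sample names are skipped with a warning and
every input record is accounted for either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .compare import SampleProfile, format_variant, profile_from_sequence
from .conservation import annotate_mutations
from .haplogroups import (
    HaplogroupAssignment,
    HaplogroupTree,
    QCVerdict,
    assign_haplogroup,
    detect_artificial_recombination,
    detect_haplotype_shift,
)
from .reference import GenomeAnnotation, ReferenceGenome
from .somatic import (
    CohortSummary,
    PatientTrio,
    SomaticMutation,
    TrioError,
    compare_trio,
    find_recurrent,
    summarize_cohort,
)


@dataclass
class PatientReport:
    patient_id: int
    trio: PatientTrio | None
    assignments: dict[str, HaplogroupAssignment]
    shift: QCVerdict
    recombination: dict[str, QCVerdict]
    mutations: list[SomaticMutation] = field(default_factory=list)
    refused: str | None = None


@dataclass
class CohortResult:
    profiles: dict[str, SampleProfile]
    patients: dict[int, PatientReport]
    summary: CohortSummary
    warnings: list[str] = field(default_factory=list)

    @property
    def mutations_by_patient(self) -> dict[int, list[SomaticMutation]]:
        return {pid: r.mutations for pid, r in self.patients.items()}

    def haplogroup_of(self, patient_id: int) -> str | None:
        report = self.patients.get(patient_id)
        if not report or not report.assignments:
            return None
        names = [a.haplogroup for a in report.assignments.values()]
        return max(set(names), key=names.count)


def read_cohort_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-FASTA of sample genomes into (name, sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def profile_cohort(
    records: list[tuple[str, str]],
    reference: ReferenceGenome,
    annotation: GenomeAnnotation,
    tree: HaplogroupTree,
) -> CohortResult:
    """Run the full somatic-profiling pipeline over named genome records."""
    profiles: dict[str, SampleProfile] = {}
    warnings: list[str] = []
    for name, seq in records:
        try:
            profiles[name] = profile_from_sequence(name, seq, reference)
        except ValueError as exc:
            warnings.append(f"skipped record {name!r}: {exc}")
    by_patient: dict[int, dict[str, SampleProfile]] = {}
    for profile in profiles.values():
        by_patient.setdefault(profile.patient_id, {})[profile.tissue] = profile
    patients: dict[int, PatientReport] = {}
    haplogroups: dict[int, str] = {}
    for pid in sorted(by_patient):
        tissue_profiles = by_patient[pid]
        assignments = {
            t: assign_haplogroup(p, tree) for t, p in tissue_profiles.items()
        }
        shift = detect_haplotype_shift(assignments)
        recomb = {
            t: detect_artificial_recombination(p, tree, assignments[t])
            for t, p in tissue_profiles.items()
        }
        report = PatientReport(
            patient_id=pid,
            trio=None,
            assignments=assignments,
            shift=shift,
            recombination=recomb,
        )
        if len(tissue_profiles) < 2:
            report.refused = "single tissue: somatic comparison not possible"
            warnings.append(f"patient {pid}: {report.refused}")
        elif shift.status == "shift":
            report.refused = "possible sample mix-up; somatic calling refused"
            warnings.append(f"patient {pid}: {report.refused}")
        else:
            trio = PatientTrio(patient_id=pid, profiles=tissue_profiles)
            report.trio = trio
            try:
                report.mutations = compare_trio(trio, qc=shift)
            except TrioError as exc:
                report.refused = str(exc)
                warnings.append(f"patient {pid}: {exc}")
            annotate_mutations(report.mutations, reference, annotation)
            names = [a.haplogroup for a in assignments.values()]
            haplogroups[pid] = max(set(names), key=names.count)
        patients[pid] = report
    called = {
        pid: r.mutations for pid, r in patients.items() if r.refused is None
    }
    summary = summarize_cohort(
        called, n_patients=len(patients), haplogroups=haplogroups
    )
    return CohortResult(
        profiles=profiles, patients=patients, summary=summary, warnings=warnings
    )


# ---------------------------------------------------------------------------
# Tabular output


def variant_table(result: CohortResult) -> pd.DataFrame:
    """Long-format per-sample variant table (kept and excluded calls)."""
    rows = []
    for profile in result.profiles.values():
        for v in profile.variants:
            rows.append(
                dict(
                    sample=profile.sample_id,
                    patient=profile.patient_id,
                    tissue=profile.tissue,
                    position=v.position,
                    ref=v.ref,
                    alleles="/".join(v.alleles) or f"+{v.inserted}",
                    kind=v.kind,
                    heteroplasmic=v.heteroplasmic,
                    excluded_by_filter="",
                )
            )
        for v, reason in profile.excluded:
            rows.append(
                dict(
                    sample=profile.sample_id,
                    patient=profile.patient_id,
                    tissue=profile.tissue,
                    position=v.position,
                    ref=v.ref,
                    alleles="/".join(v.alleles) or f"+{v.inserted}",
                    kind=v.kind,
                    heteroplasmic=v.heteroplasmic,
                    excluded_by_filter=reason,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "patient", "tissue", "position", "ref", "alleles",
            "kind", "heteroplasmic", "excluded_by_filter",
        ],
    )
    return df.sort_values(["patient", "tissue", "position"]).reset_index(drop=True)


def somatic_table(result: CohortResult) -> pd.DataFrame:
    """Per-somatic-mutation table with pattern, region, and effect."""
    recurrent = result.summary.recurrent
    rows = []
    for pid, report in sorted(result.patients.items()):
        for m in report.mutations:
            rows.append(
                dict(
                    patient=pid,
                    position=m.position,
                    state_C="|".join(m.states["C"].tokens) or "."
                    if "C" in m.states
                    else "NA",
                    state_CP="|".join(m.states["CP"].tokens) or "."
                    if "CP" in m.states
                    else "NA",
                    state_CN="|".join(m.states["CN"].tokens) or "."
                    if "CN" in m.states
                    else "NA",
                    pattern=m.pattern,
                    region=m.region,
                    effect=m.effect,
                    effect_detail=m.effect_detail or "",
                    heteroplasmic=m.heteroplasmic,
                    recurrent=m.position in recurrent,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "position", "state_C", "state_CP", "state_CN",
            "pattern", "region", "effect", "effect_detail", "heteroplasmic",
            "recurrent",
        ],
    )


def qc_report(result: CohortResult) -> dict:
    """Machine-readable QC section: shifts, recombination flags, refusals."""
    out = {}
    for pid, r in sorted(result.patients.items()):
        out[str(pid)] = dict(
            haplogroups={t: a.haplogroup for t, a in r.assignments.items()},
            shift=r.shift.status,
            shift_details=r.shift.details,
            recombination={
                t: v.status for t, v in r.recombination.items()
            },
            refused=r.refused,
        )
    return out


def summary_json(result: CohortResult) -> str:
    s = result.summary
    return json.dumps(
        dict(
            n_patients=s.n_patients,
            patients_with_cancer_tissue=s.patients_with_cancer_tissue,
            cancer_tissue_frequency=s.cancer_tissue_frequency,
            total_mutations=s.total_mutations,
            region_counts=s.region_counts,
            effect_counts=s.effect_counts,
            synonymous_sites=s.synonymous_sites,
            nonsynonymous_sites=s.nonsynonymous_sites,
            heteroplasmic_fraction=s.heteroplasmic_fraction,
            pattern_counts=s.pattern_counts,
            recurrent={str(k): list(v) for k, v in s.recurrent.items()},
        ),
        indent=2,
    )


def text_report(result: CohortResult, stats_section: str | None = None) -> str:
    """Human-readable report echoing the cohort's headline statistics."""
    s = result.summary
    lines = [
        "Somatic mtDNA mutation profile",
        "==============================",
        f"Patients analysed: {s.n_patients}",
        (
            f"Patients with cancer-tissue somatic mutation(s): "
            f"{s.patients_with_cancer_tissue}/{s.n_patients} "
            f"({100 * s.cancer_tissue_frequency:.0f}%)"
        ),
        f"Total somatic mutations: {s.total_mutations}",
        "Region breakdown: "
        + ", ".join(f"{k}={v}" for k, v in sorted(s.region_counts.items())),
        "Effect breakdown (events): "
        + ", ".join(f"{k}={v}" for k, v in sorted(s.effect_counts.items())),
        (
            f"Nonsynonymous sites: {s.nonsynonymous_sites}; "
            f"synonymous sites: {s.synonymous_sites}"
        ),
        f"Heteroplasmic fraction of somatic calls: "
        f"{100 * s.heteroplasmic_fraction:.0f}%",
        "Pattern counts: "
        + ", ".join(f"{k}={v}" for k, v in sorted(s.pattern_counts.items())),
        "Recurrent sites: "
        + (
            ", ".join(
                f"{pos} ({n} patients, {h} haplogroups)"
                for pos, (n, h) in sorted(s.recurrent.items())
            )
            or "none"
        ),
    ]
    shifted = [
        str(pid)
        for pid, r in sorted(result.patients.items())
        if r.shift.status == "shift"
    ]
    lines.append(
        "QC haplotype shifts: " + (", ".join(shifted) if shifted else "none")
    )
    if result.warnings:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in result.warnings)
    if stats_section:
        lines.append("")
        lines.append(stats_section)
    return "\n".join(lines) + "\n"


def write_outputs(result: CohortResult, outdir: str | Path) -> dict[str, Path]:
    """Write the variant table, somatic table, QC report and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "somatic": outdir / "somatic.tsv",
        "qc": outdir / "qc.json",
        "summary": outdir / "summary.json",
        "report": outdir / "report.txt",
    }
    variant_table(result).to_csv(paths["variants"], sep="\t", index=False)
    somatic_table(result).to_csv(paths["somatic"], sep="\t", index=False)
    paths["qc"].write_text(json.dumps(qc_report(result), indent=2))
    paths["summary"].write_text(summary_json(result))
    paths["report"].write_text(text_report(result))
    return paths
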