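"""Trio comparison, tissue-distribution patterns, cohort tabulation."""

import itertools

import pytest

from mitosoma.compare import SampleProfile, parse_variant
from mitosoma.haplogroups import QCVerdict
from mitosoma.somatic import (
    PatientTrio,
    TissueState,
    TrioError,
    classify_pattern,
    compare_trio,
    find_recurrent,
    summarize_cohort,
)


def trio_from_tokens(reference, patient, tokens_by_tissue):
    profiles = {}
    for tissue, tokens in tokens_by_tissue.items():
        profiles[tissue] = SampleProfile(
            f"{tissue}{patient}",
            patient,
            tissue,
            [parse_variant(t, reference) for t in tokens],
        )
    return PatientTrio(patient_id=patient, profiles=profiles)


class TestCompareTrio:
    def test_identical_tissues_yield_nothing(self, reference):
        germline = ["489", "3010"]
        trio = trio_from_tokens(
            reference, 5, {"C": germline, "CP": germline, "CN": germline}
        )
        assert compare_trio(trio) == []

    def test_homoplasmic_to_heteroplasmic_shift_in_normals(self, reference):
        """Cancer tissue homoplasmic-reference, both normal tissues C/T
        heteroplasmic: one somatic mutation, all-normal-tissues pattern."""
        trio = trio_from_tokens(
            reference,
            14,
            {"C": [], "CP": ["16093C/T"], "CN": ["16093C/T"]},
        )
        (m,) = compare_trio(trio)
        assert m.position == 16093
        assert m.pattern == "all-normal-tissues"
        assert m.heteroplasmic
        assert m.deviating == ("CP", "CN")

    def test_shared_cancer_para_heteroplasmy(self, reference):
        trio = trio_from_tokens(
            reference,
            1,
            {"C": ["6718A/G"], "CP": ["6718A/G"], "CN": []},
        )
        (m,) = compare_trio(trio)
        assert (m.pattern, m.heteroplasmic, m.invasion_flag) == (
            "cancer+para",
            True,
            True,
        )

    def test_distant_normal_only(self, reference):
        trio = trio_from_tokens(
            reference, 20, {"C": [], "CP": [], "CN": ["9275A/G"]}
        )
        (m,) = compare_trio(trio)
        assert m.pattern == "normal-only"

    def test_germline_variants_never_called_somatic(self, reference):
        germline = ["489", "3010", "8414"]
        trio = trio_from_tokens(
            reference,
            2,
            {
                "C": germline + ["6718A/G"],
                "CP": germline,
                "CN": germline,
            },
        )
        mutations = compare_trio(trio)
        assert [m.position for m in mutations] == [6718]

    def test_shift_verdict_refuses_calling(self, reference):
        trio = trio_from_tokens(reference, 3, {"C": ["489"], "CN": []})
        with pytest.raises(TrioError, match="sample mix-up"):
            compare_trio(trio, qc=QCVerdict("shift", ["tissue C"]))

    def test_two_tissue_patient(self, reference):
        trio = trio_from_tokens(reference, 19, {"C": ["16093C/T"], "CN": []})
        (m,) = compare_trio(trio)
        assert m.pattern == "cancer-only"

    def test_single_tissue_rejected(self, reference):
        with pytest.raises(TrioError, match="two tissues"):
            trio_from_tokens(reference, 7, {"C": []})


class TestClassifyPattern:
    REF = TissueState((), False)
    HET = TissueState(("16093C/T",), True)
    HOM = TissueState(("16093A",), False)

    @pytest.mark.parametrize(
        "c,cp,cn,expected",
        [
            ("HET", "REF", "REF", "cancer-only"),
            ("HET", "HET", "REF", "cancer+para"),
            ("REF", "REF", "HET", "normal-only"),
            ("REF", "HET", "HET", "all-normal-tissues"),
            ("REF", "HET", "REF", "para-only"),
            ("HOM", "REF", "REF", "cancer-only"),  # phantom-like homoplasmic
            ("HET", "REF", "HET", "other"),
        ],
    )
    def test_narrated_patterns(self, c, cp, cn, expected):
        states = {
            "C": getattr(self, c),
            "CP": getattr(self, cp),
            "CN": getattr(self, cn),
        }
        label, _, _ = classify_pattern(states)
        assert label == expected

    def test_pattern_function_is_total_over_all_state_combinations(self):
        """Every 2- and 3-tissue combination of {ref, homoplasmic,
        heteroplasmic} states yields a deterministic label."""
        alphabet = [self.REF, self.HET, self.HOM]
        labels = {
            "cancer-only", "cancer+para", "normal-only",
            "all-normal-tissues", "para-only", "other",
        }
        for combo in itertools.product(alphabet, repeat=3):
            states = dict(zip(("C", "CP", "CN"), combo))
            label1, _, _ = classify_pattern(states)
            label2, _, _ = classify_pattern(states)
            assert label1 == label2 and label1 in labels
        for combo in itertools.product(alphabet, repeat=2):
            states = dict(zip(("C", "CN"), combo))
            label, _, _ = classify_pattern(states)
            assert label in labels

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(TrioError):
            classify_pattern({"C": self.REF})


class TestRecurrence:
    def test_three_carriers_three_haplogroups(self, reference):
        cohort = {}
        for pid in (1, 8, 14):
            trio = trio_from_tokens(
                reference, pid, {"C": [], "CP": [], "CN": ["14288C/T"]}
            )
            cohort[pid] = compare_trio(trio)
        recurrent = find_recurrent(
            cohort, haplogroups={1: "D4", 8: "B4", 14: "F"}
        )
        assert recurrent == {14288: (3, 3)}

    def test_unique_positions_not_recurrent(self, reference):
        cohort = {
            1: compare_trio(
                trio_from_tokens(reference, 1, {"C": ["16093C/T"], "CN": []})
            ),
            2: compare_trio(
                trio_from_tokens(reference, 2, {"C": ["9275A/G"], "CN": []})
            ),
        }
        assert find_recurrent(cohort) == {}

    def test_same_haplogroup_counted_once(self, reference):
        cohort = {
            pid: compare_trio(
                trio_from_tokens(reference, pid, {"C": ["14288C/T"], "CN": []})
            )
            for pid in (1, 2)
        }
        assert find_recurrent(cohort, {1: "D4", 2: "D4"}) == {14288: (2, 1)}


class TestSummary:
    def test_empty_cohort_all_zero(self):
        s = summarize_cohort({}, n_patients=0)
        assert s.total_mutations == 0
        assert s.patients_with_cancer_tissue == 0
        assert s.heteroplasmic_fraction == 0.0

    def test_all_heteroplasmic_fraction_is_one(self, reference):
        cohort = {
            1: compare_trio(
                trio_from_tokens(
                    reference, 1, {"C": ["6718A/G"], "CP": [], "CN": []}
                )
            )
        }
        s = summarize_cohort(cohort)
        assert s.heteroplasmic_fraction == 1.0

    def test_cancer_tissue_patient_counting(self, reference):
        cohort = {
            1: compare_trio(
                trio_from_tokens(reference, 1, {"C": ["6718A/G"], "CP": [], "CN": []})
            ),
            2: compare_trio(
                trio_from_tokens(reference, 2, {"C": [], "CP": [], "CN": ["9275A/G"]})
            ),
            3: [],
        }
        s = summarize_cohort(cohort, n_patients=3)
        assert s.patients_with_cancer_tissue == 1
        assert s.cancer_tissue_frequency == pytest.approx(1 / 3)
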