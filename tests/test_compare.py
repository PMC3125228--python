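"""Genome alignment, variant scoring, nomenclature, exclusion filters."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mitosoma.compare import (
    MtVariant,
    TRANSITION_PARTNER,
    VariantError,
    align_to_reference,
    apply_exclusion_filters,
    apply_variants,
    call_variants,
    format_variant,
    in_exclusion_window,
    make_substitution,
    parse_sample_name,
    parse_variant,
    profile_from_sequence,
    substitution_kind,
)


def mutate(sequence: str, position: int, base: str) -> str:
    return sequence[: position - 1] + base + sequence[position:]


class TestAlignment:
    def test_identity_yields_no_variants(self, reference):
        aln = align_to_reference(reference.sequence, reference)
        assert call_variants(aln, reference) == []
        assert aln.identity(reference) == 1.0

    def test_iupac_y_pairs_both_pyrimidines(self, reference):
        # ref C at 16093; consensus Y encodes the C/T heteroplasmy
        aln = align_to_reference(mutate(reference.sequence, 16093, "Y"), reference)
        (v,) = call_variants(aln, reference)
        assert (v.position, v.alleles, v.heteroplasmic) == (16093, ("C", "T"), True)

    def test_single_deletion_called(self, reference):
        seq = reference.sequence[:248] + reference.sequence[249:]
        (v,) = call_variants(align_to_reference(seq, reference), reference)
        assert v.kind == "deletion"
        # may be right-shifted within a homopolymer; base deleted must match
        assert reference.base(v.position) == reference.base(249)

    def test_length_guard(self, reference):
        with pytest.raises(VariantError, match="length"):
            align_to_reference("ACGT" * 25, reference)

    def test_identity_guard_rejects_foreign_sequence(self, reference):
        rng = random.Random(0)
        junk = "".join(rng.choice("ACGT") for _ in range(16569))
        with pytest.raises(VariantError, match="not a human mtDNA genome"):
            align_to_reference(junk, reference)


class TestCallVariants:
    def test_homoplasmic_transition(self, reference):
        assert reference.base(4532) == "G"
        aln = align_to_reference(mutate(reference.sequence, 4532, "A"), reference)
        (v,) = call_variants(aln, reference)
        assert (v.position, v.kind, v.heteroplasmic) == (4532, "transition", False)

    def test_heteroplasmic_r_code(self, reference):
        assert reference.base(6718) == "A"
        aln = align_to_reference(mutate(reference.sequence, 6718, "R"), reference)
        (v,) = call_variants(aln, reference)
        assert v.alleles == ("A", "G") and v.heteroplasmic

    def test_multi_base_ambiguity_flagged_unresolvable(self, reference):
        aln = align_to_reference(mutate(reference.sequence, 5000, "N"), reference)
        (v,) = call_variants(aln, reference)
        assert v.unresolvable
        kept, excluded = apply_exclusion_filters([v])
        assert kept == [] and excluded[0][1] == "unresolvable ambiguity code"

    def test_transition_transversion_matches_enumeration_oracle(self):
        purines = {"A", "G"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                expected = (
                    "transition"
                    if (ref in purines) == (alt in purines)
                    else "transversion"
                )
                assert substitution_kind(ref, alt) == expected


class TestExclusionFilters:
    def test_ctract_insertion_excluded(self, reference):
        v = parse_variant("315+C", reference)
        kept, excluded = apply_exclusion_filters([v])
        assert kept == [] and excluded[0][1] == "C-tract length variation"

    def test_second_window_length_variant_excluded(self, reference):
        v = parse_variant("16189d", reference)
        kept, excluded = apply_exclusion_filters([v])
        assert kept == []

    def test_substitution_at_16189_kept(self, reference):
        assert reference.base(16189) == "T"
        v = parse_variant("16189", reference)  # T->C transition
        kept, excluded = apply_exclusion_filters([v])
        assert kept == [v] and excluded == []

    def test_windows(self):
        assert in_exclusion_window(310) and in_exclusion_window(16189)
        assert not in_exclusion_window(316) and not in_exclusion_window(16196)


class TestNomenclature:
    @pytest.mark.parametrize(
        "token,kind,het",
        [
            ("9275", "transition", False),
            ("16093A", "transversion", False),
            ("6718A/G", "transition", True),
            ("16093C/T", "transition", True),
            ("249d", "deletion", False),
            ("315+C", "insertion", False),
            ("315insC", "insertion", False),
            ("G4532A", "transition", False),
        ],
    )
    def test_parse_classifies(self, reference, token, kind, het):
        v = parse_variant(token, reference)
        assert (v.kind, v.heteroplasmic) == (kind, het)

    @pytest.mark.parametrize(
        "token", ["16093X", "", "d315", "99999", "4532G/G", "T4532A"]
    )
    def test_malformed_tokens_rejected(self, reference, token):
        with pytest.raises(VariantError):
            parse_variant(token, reference)

    def test_canonical_insertion_output(self, reference):
        assert format_variant(parse_variant("315insC", reference)) == "315+C"

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_format_parse_round_trip(self, reference, data):
        position = data.draw(st.integers(1, 16569))
        ref = reference.base(position)
        style = data.draw(st.sampled_from(["homo", "het", "del", "ins"]))
        if style == "homo":
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
            v = make_substitution(position, ref, (alt,))
        elif style == "het":
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
            second = data.draw(
                st.sampled_from([b for b in "ACGT" if b not in (alt,)])
            )
            v = make_substitution(position, ref, (alt, second))
        elif style == "del":
            v = MtVariant(position, ref, ("-",), "deletion")
        else:
            bases = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
            v = MtVariant(position, ref, (), "insertion", inserted=bases)
        assert parse_variant(format_variant(v), reference) == v


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_apply_then_recall_reproduces_variants(self, reference, seed):
        """Writing a random variant set into the reference and re-calling
        recovers it exactly (outside the excluded windows)."""
        rng = random.Random(seed)
        positions = rng.sample(
            [p for p in range(100, 16000) if not in_exclusion_window(p)],
            rng.randint(5, 50),
        )
        variants = []
        for pos in sorted(positions):
            ref = reference.base(pos)
            if rng.random() < 0.3:
                variants.append(
                    make_substitution(pos, ref, (ref, TRANSITION_PARTNER[ref]))
                )
            else:
                alt = rng.choice([b for b in "ACGT" if b != ref])
                variants.append(make_substitution(pos, ref, (alt,)))
        seq = apply_variants(reference, variants)
        called = call_variants(align_to_reference(seq, reference), reference)
        assert called == sorted(variants, key=MtVariant.sort_key)

    def test_no_heteroplasmic_call_without_ambiguity_code(self, reference):
        """A genome free of IUPAC codes can never yield heteroplasmic calls."""
        rng = random.Random(99)
        seq = list(reference.sequence)
        for pos in rng.sample(range(1, 16570), 30):
            seq[pos - 1] = rng.choice("ACGT")
        called = call_variants(
            align_to_reference("".join(seq), reference), reference
        )
        assert all(not v.heteroplasmic for v in called)


class TestSampleNames:
    @pytest.mark.parametrize(
        "name,tissue,patient",
        [("C14", "C", 14), ("CP3", "CP", 3), ("CN20", "CN", 20)],
    )
    def test_suffix_convention(self, name, tissue, patient):
        assert parse_sample_name(name) == (tissue, patient)

    @pytest.mark.parametrize("name", ["X1", "C", "CPX", "14C", "cn2"])
    def test_bad_names_rejected(self, name):
        with pytest.raises(VariantError):
            parse_sample_name(name)

    def test_profile_from_sequence(self, reference):
        seq = mutate(reference.sequence, 16093, "Y")
        profile = profile_from_sequence("CN14", seq, reference)
        assert profile.tissue == "CN" and profile.patient_id == 14
        assert [format_variant(v) for v in profile.variants] == ["16093C/T"]
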