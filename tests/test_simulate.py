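"""Synthetic cohort generator: determinism, design fidelity, truth tables."""

import numpy as np
import pytest

from mitosoma.compare import (
    align_to_reference,
    call_variants,
    format_variant,
)
from mitosoma.simulate import (
    ConfigError,
    SimulationConfig,
    inject_phantom,
    inject_swap,
    simulate_cohort,
    simulate_germline,
    simulate_population_panel,
    simulate_species_alignment,
    study_profile_cohort,
    write_cohort,
)


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_patients=0),
            dict(affected_fraction=1.5),
            dict(detection_threshold=-0.1),
            dict(muts_per_affected=(3, 1)),
            dict(minor_fraction_range=(0.0, 0.6)),
            dict(pattern_weights={"bogus": 1.0}),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs).validate()

    def test_yaml_echo_round_trips(self):
        import yaml

        cfg = SimulationConfig(seed=7, n_patients=5)
        d = yaml.safe_load(cfg.to_yaml())
        assert d["seed"] == 7 and d["n_patients"] == 5


class TestGermline:
    def test_round_trip_through_variant_calling(self, tree, reference):
        """Re-calling variants from a simulated germline genome recovers
        exactly the generating variant list."""
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(seed=3)
        haplogroup, variants, seq = simulate_germline(tree, cfg, rng, reference)
        assert haplogroup in {n.name for n in tree.leaves()}
        called = call_variants(align_to_reference(seq, reference), reference)
        assert [format_variant(v) for v in called] == [
            format_variant(v) for v in variants
        ]

    def test_zero_private_variants_gives_pure_motif(self, tree, reference):
        cfg = SimulationConfig(germline_private_range=(0, 0))
        rng = np.random.default_rng(0)
        haplogroup, variants, _ = simulate_germline(tree, cfg, rng, reference)
        expected = tree.nodes[haplogroup].expected_variants()
        assert {v.position for v in variants} == set(expected)

    def test_same_seed_same_genome(self, tree, reference):
        cfg = SimulationConfig(seed=5)
        out1 = simulate_germline(tree, cfg, np.random.default_rng(5), reference)
        out2 = simulate_germline(tree, cfg, np.random.default_rng(5), reference)
        assert out1 == out2


class TestCohort:
    def test_default_design_emits_59_genomes(self, reference, annotation, tree):
        cohort = simulate_cohort(
            SimulationConfig(seed=1), reference, annotation, tree
        )
        assert len(cohort.records) == 59
        missing_cp = [p for p in cohort.truth.patients if not p.has_cp]
        assert len(missing_cp) == 1

    def test_single_patient_full_trio(self, reference, annotation, tree):
        cfg = SimulationConfig(n_patients=1, missing_cp_probability=0.0, seed=2)
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        assert [n for n, _ in cohort.records] == ["C1", "CP1", "CN1"]

    def test_byte_identical_under_same_seed(
        self, reference, annotation, tree, tmp_path
    ):
        cfg = SimulationConfig(seed=9)
        a = write_cohort(
            simulate_cohort(cfg, reference, annotation, tree), tmp_path / "a"
        )
        b = write_cohort(
            simulate_cohort(SimulationConfig(seed=9), reference, annotation, tree),
            tmp_path / "b",
        )
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_all_somatic_events_heteroplasmic(self, reference, annotation, tree):
        cohort = simulate_cohort(
            SimulationConfig(seed=4), reference, annotation, tree
        )
        events = [e for p in cohort.truth.patients for e in p.somatic]
        assert events
        for e in events:
            assert e.ref != e.alt
            assert "/" in e.token

    def test_subthreshold_event_leaves_no_iupac_code(
        self, reference, annotation, tree
    ):
        cfg = SimulationConfig(
            seed=6,
            minor_fraction_range=(0.05, 0.10),
            detection_threshold=0.20,
            affected_fraction=1.0,
        )
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        events = [e for p in cohort.truth.patients for e in p.somatic]
        assert events and all(not e.detectable for e in events)
        for _, seq in cohort.records:
            assert set(seq) <= set("ACGT")

    def test_unaffected_patient_tissues_identical(
        self, reference, annotation, tree
    ):
        cfg = SimulationConfig(
            seed=8, affected_fraction=0.0, normal_background_rate=0.0
        )
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        by_patient = {}
        for name, seq in cohort.records:
            pid = int(name.lstrip("CPN"))
            by_patient.setdefault(pid, set()).add(seq)
        assert all(len(seqs) == 1 for seqs in by_patient.values())


class TestArtifacts:
    def test_swap_requires_two_haplogroups(self, reference, annotation, tree):
        cfg = SimulationConfig(n_patients=1, seed=3, missing_cp_probability=0)
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        with pytest.raises(ConfigError):
            inject_swap(cohort, np.random.default_rng(0))

    def test_zero_rates_leave_cohort_unchanged(self, reference, annotation, tree):
        cfg = SimulationConfig(seed=10)
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        assert all(not p.artifacts for p in cohort.truth.patients)

    def test_phantom_adds_single_homoplasmic_difference(
        self, reference, annotation, tree
    ):
        cfg = SimulationConfig(
            seed=11, affected_fraction=0.0, normal_background_rate=0.0
        )
        cohort = simulate_cohort(cfg, reference, annotation, tree)
        before = dict(cohort.records)
        (msg,) = inject_phantom(cohort, np.random.default_rng(1))
        _, name, pos = msg.split(":")
        after = dict(cohort.records)
        diffs = [
            i
            for i, (a, b) in enumerate(zip(before[name], after[name]))
            if a != b
        ]
        assert diffs == [int(pos) - 1]
        assert after[name][int(pos) - 1] in "ACGT"


class TestStudyProfileCohort:
    def test_design_counts(self, reference, annotation, tree):
        cohort = study_profile_cohort(reference, annotation, tree)
        assert len(cohort.records) == 59
        events = [e for p in cohort.truth.patients for e in p.somatic]
        assert len(events) == 18
        assert all("/" in e.token for e in events)
        carriers_14288 = {e.patient_id for e in events if e.position == 14288}
        assert len(carriers_14288) == 3

    def test_deterministic(self, reference, annotation, tree):
        a = study_profile_cohort(reference, annotation, tree)
        b = study_profile_cohort(reference, annotation, tree)
        assert a.records == b.records


class TestConservationFixtures:
    def test_species_alignment_shape_and_conserved_sites(self, reference):
        aln = simulate_species_alignment(
            reference, conserved_positions=(6718, 15447), seed=2
        )
        assert len(aln.species) == 13
        from mitosoma.conservation import interspecies_conservation

        for pos in (6718, 15447):
            index, n = interspecies_conservation(pos, aln, reference)
            assert index == 1.0 and n == 13

    def test_population_panel_hotspot_frequency(self, reference, tree):
        from mitosoma.compare import parse_variant
        from mitosoma.conservation import population_conservation

        panel = simulate_population_panel(
            reference, tree, n_genomes=300, hotspots={16093: 0.3}, seed=1
        )
        hits, freq = population_conservation(
            parse_variant("16093", reference), panel
        )
        assert 0.2 <= freq <= 0.4
        rare_hits, rare_freq = population_conservation(
            parse_variant("6718A/G", reference), panel
        )
        assert rare_freq < 0.05
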