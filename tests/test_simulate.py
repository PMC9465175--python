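"""Synthetic-mitogenome generator: determinism, conservation, round trips."""

import dataclasses

import pytest

from mitoprofile.annotation_io import GeneClass, extract_feature_sequence
from mitoprofile.arrangement import build_arrangement
from mitoprofile.composition import composition_report
from mitoprofile.reference_tables import (
    reference_annotation_table,
    reference_codon_counts,
    reference_codon_usage,
)
from mitoprofile.simulate import (
    ANCESTRAL_INSECT_ORDER,
    ControlRegionPlan,
    SimulationConfig,
    TruthManifest,
    generate,
    write_outputs,
)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_output(self):
        g1, t1, m1 = generate(SimulationConfig(seed=3))
        g2, t2, m2 = generate(SimulationConfig(seed=3))
        assert g1.seq == g2.seq
        assert t1.features == t2.features
        assert m1.to_json() == m2.to_json()

    def test_different_seeds_differ(self):
        g1, _, _ = generate(SimulationConfig(seed=1))
        g2, _, _ = generate(SimulationConfig(seed=2))
        assert g1.seq != g2.seq


class TestConservation:
    def test_genome_length_equals_manifest(self, default_sim):
        genome, table, manifest = default_sim
        assert genome.length == manifest.genome_length == table.genome_length

    def test_gene_complement(self, default_sim):
        _, table, _ = default_sim
        assert len(table.by_class(GeneClass.PCG)) == 13
        assert len(table.by_class(GeneClass.TRNA)) == 22
        assert len(table.by_class(GeneClass.RRNA)) == 2
        assert len(table.by_class(GeneClass.CONTROL_REGION)) == 1

    def test_custom_overlap_recovered_by_arrangement(self):
        cfg = SimulationConfig(seed=2)
        cfg.junction_plants = dict(cfg.junction_plants)
        del cfg.junction_plants[("atp8", "atp6")]
        cfg.gaps = {**cfg.gaps, ("atp8", "atp6"): -9}
        _, table, manifest = generate(cfg)
        rows = {r.name: r for r in build_arrangement(table)}
        assert rows["atp8"].ign_next == -9
        assert manifest.gaps["atp8|atp6"] == -9

    def test_inconsistent_overlap_rejected_before_generation(self):
        cfg = SimulationConfig(seed=1)
        cfg.junction_plants = dict(cfg.junction_plants)
        del cfg.junction_plants[("atp8", "atp6")]  # plant would re-impose -7
        cfg.gaps = {**cfg.gaps, ("atp8", "atp6"): -200}  # larger than atp8
        with pytest.raises(ValueError, match="overlap"):
            generate(cfg)

    def test_pcg_length_stop_consistency_enforced(self):
        bad = list(ANCESTRAL_INSECT_ORDER)
        i = next(i for i, g in enumerate(bad) if g.name == "cox1")
        bad[i] = dataclasses.replace(bad[i], length=1535)  # not 0 mod 3 for TAA
        with pytest.raises(ValueError, match="cox1"):
            generate(SimulationConfig(seed=1, gene_order=tuple(bad)))


class TestComposition:
    def test_class_at_content_near_targets(self, default_sim):
        genome, table, _ = default_sim
        cfg = SimulationConfig()
        rows = {r.label: r for r in composition_report(genome, table)}
        assert rows["rRNA"].pct_at == pytest.approx(100 * cfg.rrna_target_at, abs=0.5)
        assert rows["A+T region"].pct_at == pytest.approx(
            100 * cfg.control_region.target_at, abs=1.5
        )

    def test_pcg_at_matches_codon_weight_expectation(self, default_sim):
        genome, table, _ = default_sim
        counts = reference_codon_counts()  # the default codon weights
        total_nt = 3 * sum(counts.values())
        at = sum(n * (c.count("A") + c.count("U")) for c, n in counts.items())
        expected = 100 * at / total_nt
        rows = {r.label: r for r in composition_report(genome, table)}
        assert rows["PCG"].pct_at == pytest.approx(expected, abs=1.5)

    def test_whole_genome_is_at_rich_like_an_insect_mitogenome(self, default_sim):
        genome, table, _ = default_sim
        rows = {r.label: r for r in composition_report(genome, table)}
        assert 73 <= rows["Whole genome"].pct_at <= 80


class TestControlRegionPlan:
    def test_poly_t_and_ta_copies_configurable(self):
        cfg = SimulationConfig(seed=5, control_region=ControlRegionPlan(
            poly_t=15, ta_copies=7))
        _, _, manifest = generate(cfg)
        kinds = {(p["kind"], p["unit"]): p for p in manifest.control_region_plants}
        assert kinds[("homopolymer", "T")]["length"] == 15
        assert kinds[("microsatellite", "AT")]["copies"] == 7

    def test_region_too_short_for_plants_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate(SimulationConfig(
                seed=1, control_region=ControlRegionPlan(length=150)))


class TestManifestRoundTrip:
    def test_manifest_json_round_trip(self, default_sim):
        _, _, manifest = default_sim
        back = TruthManifest.from_json(manifest.to_json())
        assert back.genome_length == manifest.genome_length
        assert back.codon_counts == manifest.codon_counts

    def test_write_outputs_emits_all_files(self, default_sim, tmp_path):
        genome, table, manifest = default_sim
        write_outputs(genome, table, manifest, tmp_path)
        for name in ("genome.fasta", "annotation.tsv", "genome.gb", "manifest.json"):
            assert (tmp_path / name).exists()

    def test_full_recovery_for_seeds_1_to_5(self, sims_1_to_5):
        """Coordinates, gaps, plants and junction motifs all recompute exactly."""
        from mitoprofile.control_region import region_report
        from mitoprofile.junction_motifs import junction_window, motif_scan

        for seed, (genome, table, manifest) in sims_1_to_5.items():
            rows = build_arrangement(table)
            by_name = {f["name"]: f for f in manifest.features}
            for r in rows:
                f = by_name[r.name]
                assert (r.start, r.end, r.size) == (f["start"], f["end"], f["size"])
            gaps = {tuple(k.split("|")): v for k, v in manifest.gaps.items()}
            names = [r.name for r in rows]
            for i, r in enumerate(rows):
                assert r.ign_next == gaps.get((r.name, names[(i + 1) % len(rows)]), 0)
            rep = region_report(genome, table)
            got = [(x.kind, x.start, x.length, x.unit, x.copies, x.mate_start)
                   for x in rep.features]
            want = [(p["kind"], p["start"], p["length"], p["unit"], p["copies"],
                     p["mate_start"]) for p in manifest.control_region_plants]
            assert got == want
            for key, motif in manifest.junction_plants.items():
                a, b = key.split("|")
                w = junction_window(genome, table, a, b)
                assert not motif_scan([w], motif).empty


class TestReferenceFixtures:
    def test_annotation_row_count_and_cox1(self):
        t = reference_annotation_table()
        assert len(t.features) == 38
        cox1 = t.feature("cox1")
        assert (cox1.start, cox1.end) == (1392, 2925)

    def test_positive_printed_ign_count_is_15(self):
        t = reference_annotation_table()
        assert sum(1 for v in t.ign if v is not None and v > 0) == 15

    def test_codon_counts_spot_values_and_total(self):
        counts = reference_codon_counts()
        assert counts["UUA"] == 199
        assert counts["GCG"] == 1
        assert len(counts) == 64
        assert sum(counts.values()) == 3698

    def test_printed_rscu_covers_all_codons(self):
        _, printed, labels = reference_codon_usage()
        assert len(printed) == 64
        assert labels["UUA"] == "L"
        assert labels["UAA"] == ""
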