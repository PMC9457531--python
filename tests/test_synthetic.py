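import numpy as np
import pytest

from orthopath import community, io_formats as io, simulate
from orthopath.alignment import six_frame_translate


class TestMutateProtein:
    def test_target_hundred_is_identity(self):
        seq = simulate.random_protein(100, np.random.default_rng(1))
        mutated, realized = simulate.mutate_protein(seq, 100.0, seed=5)
        assert mutated == seq and realized == 100.0

    def test_realized_identity_by_direct_count(self):
        seq = simulate.random_protein(200, np.random.default_rng(1))
        mutated, realized = simulate.mutate_protein(seq, 60.0, seed=7)
        counted = 100.0 * sum(a == b for a, b in zip(seq, mutated)) / len(seq)
        assert counted == realized
        assert 58.0 <= counted <= 62.0

    def test_unreachable_target_on_short_sequence(self):
        with pytest.raises(ValueError, match="unreachable"):
            simulate.mutate_protein("MKVLAMKVLA", 5.0, seed=1)

    def test_deterministic_per_seed(self):
        seq = simulate.random_protein(80, np.random.default_rng(2))
        assert simulate.mutate_protein(seq, 50, 3) == simulate.mutate_protein(seq, 50, 3)
        assert simulate.mutate_protein(seq, 50, 3) != simulate.mutate_protein(seq, 50, 4)


class TestPlantGene:
    def test_plant_then_translate_recovers_protein(self, rng):
        protein = simulate.random_protein(60, rng)
        genome = "".join(rng.choice(list("ACGT"), 1000))
        for strand in "+-":
            planted, frame = simulate.plant_gene(genome, protein, strand, 300, seed=9)
            rec = io.SequenceRecord("c", "", planted, io.NUCLEOTIDE)
            frames = {
                (f.strand, f.frame): f.residues for f in six_frame_translate(rec)
            }
            assert protein in frames[(strand, frame)]

    def test_minus_strand_plant_not_on_plus_strand(self, rng):
        protein = simulate.random_protein(60, rng)  # >= 50 aa
        genome = "".join(rng.choice(list("ACGT"), 1000))
        planted, _ = simulate.plant_gene(genome, protein, "-", 300, seed=9)
        rec = io.SequenceRecord("c", "", planted, io.NUCLEOTIDE)
        plus = [f.residues for f in six_frame_translate(rec) if f.strand == "+"]
        assert not any(protein in res for res in plus)

    def test_synonymous_codon_choice_differs_by_seed(self, rng):
        protein = simulate.random_protein(60, rng)
        genome = "A" * 1000
        g1, _ = simulate.plant_gene(genome, protein, "+", 0, seed=1)
        g2, _ = simulate.plant_gene(genome, protein, "+", 0, seed=2)
        assert g1 != g2
        from orthopath.alignment import translate

        assert translate(g1[: 180], 0, "+") == translate(g2[: 180], 0, "+")

    def test_flanks_untouched(self, rng):
        protein = simulate.random_protein(20, rng)
        genome = "".join(rng.choice(list("ACGT"), 500))
        planted, _ = simulate.plant_gene(genome, protein, "+", 100, seed=3)
        assert planted[:100] == genome[:100]
        assert planted[160:] == genome[160:]

    def test_out_of_room_rejected(self, rng):
        protein = simulate.random_protein(60, rng)
        with pytest.raises(ValueError, match="room"):
            simulate.plant_gene("ACGT" * 20, protein, "+", 0, seed=1)

    def test_builder_rejects_overlap(self, rng):
        b = simulate.GenomeBuilder("c", 2000, rng)
        protein = simulate.random_protein(50, rng)
        b.plant(protein, "+", position=100)
        with pytest.raises(ValueError, match="overlap"):
            b.plant(protein, "+", position=200)  # 100..250 still occupied


class TestScenario:
    def test_deterministic_under_seed(self):
        cfg = simulate.ScenarioConfig(seed=7, genome_length=5000,
                                      n_isolates=2, enzyme_length=60)
        a = simulate.generate_scenario(cfg)
        b = simulate.generate_scenario(cfg)
        assert [e.record.residues for e in a.enzymes] == [
            e.record.residues for e in b.enzymes
        ]
        for gid in a.genomes:
            assert a.genomes[gid][0].residues == b.genomes[gid][0].residues

    def test_truth_structure_matches_config(self):
        cfg = simulate.ScenarioConfig(seed=3, genome_length=8000,
                                      n_isolates=3, enzyme_length=60)
        sc = simulate.generate_scenario(cfg)
        assert sc.truth.expected_essential_candidates == ["9"]
        enriched = [r for r in sc.roles if r.role == "enriched_genus"]
        assert len(enriched) == 1 and enriched[0].genus == "Methylotenera"
        planted = sc.truth.planted[enriched[0].genome_id]
        assert {p.enzyme_id for p in planted} == {"1", "2", "3", "9", "24"}
        for gid in [r.genome_id for r in sc.roles if r.role == "nondegrader_isolate"]:
            assert {p.enzyme_id for p in sc.truth.planted[gid]} == {"1", "2", "3", "24"}

    def test_bad_subset_label_rejected(self):
        with pytest.raises(ValueError, match="outside pathway"):
            simulate.ScenarioConfig(n_enzymes=5, enriched_enzyme_subset=("9",),
                                    isolate_enzyme_subset=("1",))

    def test_written_scenario_passes_io_validation(self, tmp_path):
        cfg = simulate.ScenarioConfig(seed=5, genome_length=4000,
                                      n_isolates=1, enzyme_length=50,
                                      enriched_enzyme_subset=("1", "9"),
                                      isolate_enzyme_subset=("1",))
        sc = simulate.generate_scenario(cfg)
        simulate.write_scenario(sc, tmp_path)
        enz = io.read_fasta(tmp_path / "enzymes.faa", io.PROTEIN)
        assert len(enz) == cfg.n_enzymes
        for gid in sc.genomes:
            recs = io.read_fasta(tmp_path / "genomes" / f"{gid}.fna", io.NUCLEOTIDE)
            assert len(recs[0]) == cfg.genome_length
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "roles.tsv").exists()


class TestCommunityGenerator:
    def test_deterministic_under_seed(self):
        t1, c1 = simulate.generate_community_series(seed=11)
        t2, c2 = simulate.generate_community_series(seed=11)
        for s in t1:
            for g in t1[s].counts:
                assert np.array_equal(t1[s].counts[g], t2[s].counts[g])
            assert np.array_equal(c1[s].concentrations, c2[s].concentrations)

    def test_focal_genus_peaks_on_day_three_in_degrading_samples(self):
        tables, curves = simulate.generate_community_series(seed=4)
        cfg = simulate.CommunityConfig()
        for name, table in tables.items():
            label, _ = community.classify_degradation(curves[name])
            s = community.relative_abundance(table)
            if label == "degraded":
                traj = s.abundance[cfg.focal_genus]
                assert s.timepoints[int(np.argmax(traj))] == 3

    def test_stable_samples_classify_stable(self):
        _, curves = simulate.generate_community_series(seed=8)
        labels = {
            name: community.classify_degradation(c)[0] for name, c in curves.items()
        }
        assert sum(v == "stable" for v in labels.values()) == 3
        assert sum(v == "degraded" for v in labels.values()) == 3

    def test_generated_tables_round_trip_through_io(self, tmp_path):
        tables, curves = simulate.generate_community_series(seed=2)
        simulate.write_community_series(tables, curves, tmp_path)
        for name in tables:
            t = io.read_genus_counts(tmp_path / f"{name}_counts.tsv", name)
            assert t.timepoints == list(simulate.CommunityConfig().timepoints)
            io.read_degradation_curve(tmp_path / f"{name}_curve.tsv", name)

    def test_low_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            simulate.CommunityConfig(depth=50)


class TestHitTableGenerator:
    def test_composition_matches_parameters(self):
        hits = simulate.generate_hit_table(seed=0)
        assert len(hits) == 500
        resolved = [h for h in hits if h.genus is not None]
        assert len(resolved) == 219
        focal = [h for h in resolved if h.genus == "Methylotenera"]
        assert len(focal) == 11
        from collections import Counter

        counts = Counter(h.genus for h in resolved)
        assert counts.most_common(1)[0][0] == "Variovorax"

    def test_records_are_valid_and_unique(self):
        hits = simulate.generate_hit_table(seed=1)
        assert len({h.subject_id for h in hits}) == len(hits)
        assert all(0 <= h.similarity_pct <= 100 for h in hits)
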