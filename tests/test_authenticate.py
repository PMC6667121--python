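"""Composition metrics, junction analysis and damage profiles."""

import math

import numpy as np
import pytest

from paleorna import (
    build_junction_index,
    calibrate_length_ratio,
    count_junction_straddlers,
    damage_profile,
    duplication_rate,
    endogenous_percent,
    enrichment_factor,
    rrna_proportion,
)
from paleorna.align import Alignment, AlignmentSet, map_reads
from paleorna.authenticate import (
    JunctionCounts,
    MappingCounts,
    count_mappings,
    junction_enrichment,
    read_mapping_summary,
)
from paleorna.pipeline import packaged_mapping_summary, packaged_mapping_summary_frame
from paleorna.reference import GeneModel
from paleorna.simulate import (
    DamageModel,
    FragmentLengthModel,
    SimulationConfig,
    alignments_from_truth,
    simulate_sample,
)

from conftest import brute_force_straddlers


def _counts(T, G, M, R, tR):
    return MappingCounts("s", "p", T, G, M, R, tR)


class TestComposition:
    def test_endogenous_percent_published_rows(self):
        assert endogenous_percent(_counts(23258645, 11366481, 0, 0, 0)) == 48.87
        assert endogenous_percent(_counts(6811527, 4114476, 0, 0, 0)) == 60.40

    def test_endogenous_zero_genome(self):
        assert endogenous_percent(_counts(100, 0, 0, 0, 0)) == 0.0
        assert math.isnan(endogenous_percent(_counts(0, 0, 0, 0, 0)))

    def test_rrna_proportion_published_rows(self):
        c = _counts(23258645, 11366481, 3493902, 7612932, 1441633)
        assert rrna_proportion(c) == 31.83
        c = _counts(1701272, 56822, 20808, 126467, 24069)
        assert rrna_proportion(c) == 55.43

    def test_rrna_zero(self):
        assert rrna_proportion(_counts(30, 10, 10, 0, 10)) == 0.0
        assert math.isnan(rrna_proportion(_counts(0, 0, 0, 0, 0)))

    def test_enrichment_equal_frequencies_is_one(self):
        c = _counts(1000, 100, 100, 0, 0)
        assert enrichment_factor(c, 5000, 5000) == pytest.approx(1.0)

    def test_enrichment_hand_arithmetic(self):
        # 200 RNA reads on 1 kb of transcripts vs 100 genome reads on 10 kb
        c = _counts(1000, 100, 200, 0, 0)
        assert enrichment_factor(c, 10_000, 1_000) == pytest.approx(20.0)

    def test_enrichment_zero_genome_flagged(self):
        assert math.isnan(enrichment_factor(_counts(10, 0, 5, 0, 0), 10, 10))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            _counts(10, 20, 0, 0, 0)  # genome > total

    def test_duplication_rate(self):
        assert duplication_rate(["a", "a", "b"]) == pytest.approx(1 / 3)
        assert duplication_rate(["a", "b", "c"]) == 0.0
        assert math.isnan(duplication_rate([]))


class TestMappingSummaryFixture:
    def test_round_trips_through_io(self, tmp_path):
        df = packaged_mapping_summary_frame()
        path = tmp_path / "summary.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_mapping_summary(path)
        counts = packaged_mapping_summary()
        assert len(back) == len(counts) == 12
        assert [c.total_reads for c in back] == [c.total_reads for c in counts]

    def test_hiseq_skin1_row_values(self):
        counts = {
            (c.platform, c.sample_id): c for c in packaged_mapping_summary()
        }
        c = counts[("HiSeq", "Skin 1")]
        assert (c.total_reads, c.genome) == (23258645, 11366481)
        assert endogenous_percent(c) == 48.87
        assert rrna_proportion(c) == 31.83

    def test_enrichment_factor_calibrated_across_rows(self):
        counts = {
            (c.platform, c.sample_id): c for c in packaged_mapping_summary()
        }
        ratio = calibrate_length_ratio(counts[("HiSeq", "Skin 2")], 14.36)
        skin1 = counts[("HiSeq", "Skin 1")]
        assert round(enrichment_factor(skin1, ratio, 1.0), 2) == 15.18


class TestCountMappings:
    def test_missing_class_raises(self):
        sets = {c: AlignmentSet("s", c, []) for c in ("genome", "mRNA", "rRNA")}
        with pytest.raises(KeyError, match="tRNA"):
            count_mappings("s", 0, sets)

    def test_empty_read_set_all_zero(self):
        sets = {c: AlignmentSet("s", c, [])
                for c in ("genome", "mRNA", "rRNA", "tRNA")}
        c = count_mappings("s", 0, sets)
        assert (c.genome, c.mrna, c.rrna, c.trna) == (0, 0, 0, 0)

    def test_simulated_counts_match_truth_within_mapper_loss(self, ref):
        cfg = SimulationConfig(
            seed=61, n_reads=5000, tissue="liver", rrna_frac=0.3,
            trna_frac=0.05, dna_contam_frac=0.1,
            damage=DamageModel(0.0, 0.5, 0.0), seq_error=0.0,
        )
        reads, truth = simulate_sample(ref, cfg)
        sets = {
            cls: map_reads(reads, ref.reference_sequences(cls), cls)
            for cls in ("genome", "mRNA", "rRNA", "tRNA")
        }
        c = count_mappings("s", len(reads), sets)
        t = truth.class_counts()
        # every simulated RNA read should map to its own class; allow 2% loss
        assert c.mrna >= 0.98 * t["mRNA"]
        assert c.rrna >= 0.98 * t["rRNA"]
        assert c.trna >= 0.98 * t["tRNA"]


class TestJunctions:
    def test_index_from_exon_lengths(self):
        g = GeneModel("g", "+", ((0, 50), (100, 130), (200, 220)), "mRNA")
        idx = build_junction_index([g])
        assert idx.exon_exon["g"] == (50, 80)
        assert idx.splice["g"] == (50, 100, 130, 200)

    def test_single_exon_gene_has_no_junctions(self):
        g = GeneModel("g", "+", ((0, 50),), "mRNA")
        idx = build_junction_index([g])
        assert idx.exon_exon["g"] == ()
        assert idx.splice["g"] == ()

    def test_index_size_matches_annotation(self, ref):
        idx = build_junction_index(ref.genes)
        assert idx.n_exon_exon == sum(len(g.exons) - 1 for g in ref.genes)
        assert idx.n_splice == sum(2 * (len(g.exons) - 1) for g in ref.genes)

    def test_straddle_boundary_rules(self):
        g = GeneModel("g", "+", ((0, 50), (100, 150)), "mRNA")
        idx = build_junction_index([g])

        def count(start, end, overhang):
            aset = AlignmentSet("s", "mRNA", [
                Alignment("r", "g", start, end, "+", "A" * (end - start))
            ])
            return count_junction_straddlers(aset, None, idx, overhang).exon_exon

        assert count(45, 55, 5) == 1   # exactly min_overhang on both sides
        assert count(0, 50, 1) == 0    # touches but does not cross
        assert count(46, 55, 5) == 0   # too little 5' overhang

    def test_read_crossing_multiple_junctions_counted_once(self):
        g = GeneModel("g", "+", ((0, 20), (60, 80), (120, 140)), "mRNA")
        idx = build_junction_index([g])
        aset = AlignmentSet("s", "mRNA", [
            Alignment("r", "g", 0, 60, "+", "A" * 60)  # crosses EE at 20 and 40
        ])
        assert count_junction_straddlers(aset, None, idx, 1).exon_exon == 1

    def test_matches_bruteforce_on_simulated_rna(self, ref):
        cfg = SimulationConfig(
            seed=67, n_reads=4000, tissue="skin",
            damage=DamageModel(0.0, 0.5, 0.0), seq_error=0.0,
        )
        reads, _ = simulate_sample(ref, cfg)
        aln = map_reads(reads, ref.reference_sequences("mRNA"), "mRNA")
        idx = build_junction_index(ref.genes)
        got = count_junction_straddlers(aln, None, idx, 1)
        assert got.exon_exon == brute_force_straddlers(aln, idx.exon_exon, 1)
        assert got.exon_exon > 0

    def test_rna_vs_dna_fold_pattern(self, ref):
        idx = build_junction_index(ref.genes)
        rna_cfg = SimulationConfig(
            seed=71, n_reads=4000, tissue="skin",
            damage=DamageModel(0.0, 0.5, 0.0), seq_error=0.0,
        )
        dna_cfg = SimulationConfig(
            seed=73, n_reads=4000, tissue="skin", dna_contam_frac=1.0,
            damage=DamageModel(0.0, 0.5, 0.0), seq_error=0.0,
        )
        folds = {}
        for label, cfg in (("RNA", rna_cfg), ("DNA", dna_cfg)):
            reads, _ = simulate_sample(ref, cfg)
            taln = map_reads(reads, ref.reference_sequences("mRNA"), "mRNA")
            galn = map_reads(reads, {"chr1": ref.genome}, "genome")
            folds[label] = count_junction_straddlers(taln, galn, idx, 1)
        report = junction_enrichment(folds["RNA"], folds["DNA"])
        rna_fold = report.loc[report.molecule == "RNA", "fold"].iloc[0]
        dna_fold = report.loc[report.molecule == "DNA", "fold"].iloc[0]
        assert rna_fold > 1 > dna_fold
        assert folds["DNA"].splice > folds["DNA"].exon_exon

    def test_fold_arithmetic(self):
        assert JunctionCounts("s", 186, 1, 1).fold == 186
        assert JunctionCounts("s", 5, 5, 1).fold == 1.0
        assert JunctionCounts("s", 3, 0, 1).fold == math.inf


class TestDamageProfile:
    def test_no_damage_no_error_all_zero(self, ref):
        cfg = SimulationConfig(
            seed=79, n_reads=1000, tissue="liver",
            damage=DamageModel(0.0, 0.5, 0.0), seq_error=0.0,
        )
        reads, truth = simulate_sample(ref, cfg)
        aln = alignments_from_truth(reads, truth, ref, ("mRNA",))
        prof = damage_profile(aln, ref.reference_sequences("mRNA"))
        freqs = prof.table["frequency"].dropna()
        assert (freqs == 0).all()

    def test_hand_built_fixture_exact_frequency(self):
        # reference CCA AGT; three reads covering [0,6), one with C->T at
        # read position 2
        refs = {"t": "CCAAGT"}
        reads = ["CCAAGT", "CCAAGT", "CCTAGT"]
        alns = [
            Alignment(f"r{i}", "t", 0, 6, "+", s,
                      mismatches=((2, "A", "T"),) if s[2] == "T" else ())
            for i, s in enumerate(reads)
        ]
        # the mismatch at position 2 is A>T here; use position 1 C>T instead
        alns[2] = Alignment("r2", "t", 0, 6, "+", "CTAAGT",
                            mismatches=((1, "C", "T"),))
        aset = AlignmentSet("s", "mRNA", alns)
        prof = damage_profile(aset, refs, span=6)
        # position 1 from 5': 3 reference Cs seen, 1 C>T
        assert prof.frequency("5p", 1, "C>T") == pytest.approx(1 / 3)
        assert prof.frequency("5p", 0, "C>T") == 0.0
        # same event is 4 from the 3' end
        assert prof.frequency("3p", 4, "C>T") == pytest.approx(1 / 3)

    def test_zero_opportunity_positions_are_missing_not_zero(self):
        refs = {"t": "AAAA"}
        aset = AlignmentSet("s", "mRNA", [
            Alignment("r", "t", 0, 4, "+", "AAAA")
        ])
        prof = damage_profile(aset, refs, span=4)
        assert math.isnan(prof.frequency("5p", 0, "C>T"))
        assert prof.frequency("5p", 0, "A>G") == 0.0

    def test_parameter_recovery_and_no_g_to_a(self, ref):
        cfg = SimulationConfig(
            seed=83, n_reads=30_000, tissue="liver",
            frag=FragmentLengthModel(weight_ultrashort=0.0, long_range=(30, 80)),
            damage=DamageModel(delta_max=0.3, decay=0.5, flat_rate=0.01),
            seq_error=0.0,
        )
        reads, truth = simulate_sample(ref, cfg)
        aln = alignments_from_truth(reads, truth, ref, ("mRNA",))
        prof = damage_profile(aln, ref.reference_sequences("mRNA"))
        assert prof.frequency("5p", 0, "C>T") == pytest.approx(0.31, abs=0.02)
        ga = prof.series("5p", "G>A")[:10]
        assert np.nanmax(ga) < 0.005

    def test_monotone_decay_when_flat_component_zero(self, ref):
        cfg = SimulationConfig(
            seed=89, n_reads=40_000, tissue="liver",
            frag=FragmentLengthModel(weight_ultrashort=0.0, long_range=(40, 80)),
            damage=DamageModel(delta_max=0.4, decay=0.5, flat_rate=0.0),
            seq_error=0.0,
        )
        reads, truth = simulate_sample(ref, cfg)
        aln = alignments_from_truth(reads, truth, ref, ("mRNA",))
        prof = damage_profile(aln, ref.reference_sequences("mRNA"))
        ct = prof.series("5p", "C>T")[:10]
        # sampling noise allowance on a strictly decaying expectation
        assert all(ct[i + 1] <= ct[i] + 0.005 for i in range(9))


def test_per_junction_normalised_enrichment():
    g = GeneModel("g", "+", ((0, 50), (100, 150), (200, 250)), "mRNA")
    idx = build_junction_index([g])  # 2 EE junctions, 4 SJ boundaries
    rna = JunctionCounts("rna", 8, 2, 1)
    dna = JunctionCounts("dna", 1, 8, 1)
    raw = junction_enrichment(rna, dna)
    norm = junction_enrichment(rna, dna, index=idx, per_junction=True)
    assert raw.loc[0, "fold"] == pytest.approx(4.0)
    # (8/2) / (2/4) = 8-fold after per-junction normalisation
    assert norm.loc[0, "fold"] == pytest.approx(8.0)
    with pytest.raises(ValueError):
        junction_enrichment(rna, dna, per_junction=True)
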