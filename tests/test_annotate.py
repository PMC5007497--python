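import numpy as np
import pytest

import fixtures as fx

from p53re.annotate import (
    GeneModel,
    RepeatFeature,
    SummaryStats,
    TranscriptModel,
    annotations_to_dataframe,
    apply_repeat_overlap,
    associate_genes,
    classify_region,
    load_annotation,
    load_repeats,
    repeat_overlap,
    strand_concordant,
    summarize,
)
from p53re.pattern import MatchSet, MotifMatch, compile_pattern, scan_genome
from p53re.simulate import SimulationConfig, gen_gene_models, write_gff3


def _match(start, end, chrom="chr1", spacer=None):
    spacer = (end - start) - 20 if spacer is None else spacer
    return MotifMatch(chrom, start, end, spacer, "+", "N" * (end - start))


def _simple_gene(start=10_000, end=12_000, strand="+", chrom="chr1"):
    tx = TranscriptModel("t1", strand, start, end, exons=[(start, end)])
    return GeneModel("g1", "g1", "protein_coding", chrom, strand, start, end, [tx])


TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t1001\t3000\t.\t+\t.\tID=geneX;Name=geneX;biotype=protein_coding
chr1\ttest\tmRNA\t1001\t3000\t.\t+\t.\tID=txX;Parent=geneX
chr1\ttest\texon\t1001\t1500\t.\t+\t.\tID=txX.e1;Parent=txX
chr1\ttest\texon\t2001\t3000\t.\t+\t.\tID=txX.e2;Parent=txX
chr1\ttest\tgene\t5001\t5200\t.\t-\t.\tID=geneY;biotype=miRNA
chr1\ttest\ttranscript\t5001\t5200\t.\t-\t.\tID=txY;Parent=geneY
chr1\ttest\texon\t5001\t5200\t.\t-\t.\tID=txY.e1;Parent=txY
"""


class TestLoadAnnotation:
    def test_toy_gff_hierarchy(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(TOY_GFF)
        genes = load_annotation(p)
        assert [g.gene_id for g in genes] == ["geneX", "geneY"]
        gx = genes[0]
        assert (gx.start, gx.end, gx.strand) == (1000, 3000, "+")
        tx = gx.transcripts[0]
        assert tx.exons == [(1000, 1500), (2000, 3000)]  # intron inferable between
        assert genes[1].biotype == "miRNA"

    def test_synthetic_gff_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=8, chrom_length=500_000, n_genes=50, n_chroms=2)
        genes = gen_gene_models(cfg)
        path = tmp_path / "sim.gff3"
        write_gff3(genes, path)
        loaded = load_annotation(path)
        assert len(loaded) == len(genes)
        for a, b in zip(genes, loaded):
            assert (a.gene_id, a.chrom, a.start, a.end, a.strand, a.biotype) == (
                b.gene_id, b.chrom, b.start, b.end, b.strand, b.biotype
            )
            ta, tb = a.transcripts[0], b.transcripts[0]
            assert ta.exons == tb.exons
            assert ta.five_prime_utr == tb.five_prime_utr
            assert ta.three_prime_utr == tb.three_prime_utr


class TestAssociateGenes:
    def test_upstream_association_within_window(self):
        gene = _simple_gene(10_000, 12_000, "+")
        anns = associate_genes([_match(6_000, 6_020)], [gene])
        assert len(anns) == 1
        assert anns[0].region_label == "upstream"
        # nearest match edge is the last base (0-based 6019): 6019 - 10000
        assert anns[0].distance_to_tss == -3_981

    def test_far_pattern_not_associated(self):
        gene = _simple_gene(10_000, 12_000)
        assert associate_genes([_match(1_000, 1_020)], [gene]) == []

    def test_pattern_in_two_windows_gets_two_annotations(self):
        g1 = _simple_gene(10_000, 12_000)
        g2 = _simple_gene(13_000, 15_000)
        g2.gene_id = g2.symbol = "g2"
        anns = associate_genes([_match(12_400, 12_420)], [g1, g2])
        assert len(anns) == 2
        assert all(a.n_genes_for_pattern == 2 for a in anns)

    def test_window_boundary_is_inclusive_overlap(self):
        gene = _simple_gene(10_000, 12_000)
        # ends exactly at the window edge (5000 - 20)
        assert len(associate_genes([_match(4_980, 5_000)], [gene])) == 0
        assert len(associate_genes([_match(4_981, 5_001)], [gene])) == 1


class TestClassifyRegion:
    def _gene(self):
        tx = TranscriptModel(
            "t1", "+", 10_000, 20_000,
            exons=[(10_000, 11_000), (12_000, 13_000), (14_000, 20_000)],
            five_prime_utr=[(10_000, 10_200)],
            three_prime_utr=[(19_500, 20_000)],
        )
        return GeneModel("g", "g", "protein_coding", "chr1", "+", 10_000, 20_000, [tx])

    def test_exon_interior(self):
        label, _ = classify_region(_match(12_100, 12_130), self._gene())
        assert label == "exon"

    def test_intron_between_exons(self):
        label, _ = classify_region(_match(11_200, 11_230), self._gene())
        assert label == "intron"

    def test_five_prime_utr_beats_exon(self):
        label, _ = classify_region(_match(10_100, 10_130), self._gene())
        assert label == "five_prime_UTR"

    def test_upstream_with_signed_distance(self):
        label, dist = classify_region(_match(9_780, 9_800), self._gene())
        assert label == "upstream"
        assert dist == -201  # nearest edge 9799 vs TSS 10000

    def test_downstream_past_gene_end(self):
        label, dist = classify_region(_match(20_500, 20_520), self._gene())
        assert label == "downstream" and dist > 0

    def test_minus_strand_upstream_is_right_of_gene(self):
        tx = TranscriptModel("t1", "-", 10_000, 20_000, exons=[(10_000, 20_000)])
        gene = GeneModel("g", "g", "protein_coding", "chr1", "-", 10_000, 20_000, [tx])
        label, dist = classify_region(_match(20_980, 21_000), gene)
        assert label == "upstream"
        assert dist == -981  # TSS at 19999, nearest edge 20980

    def test_representative_transcript_is_longest(self):
        short = TranscriptModel("a_short", "+", 10_000, 11_000,
                                exons=[(10_000, 11_000)])
        long = TranscriptModel("b_long", "+", 10_000, 20_000,
                               exons=[(10_000, 10_100), (19_000, 20_000)])
        gene = GeneModel("g", "g", "protein_coding", "chr1", "+",
                         10_000, 20_000, [short, long])
        assert gene.representative_transcript.transcript_id == "b_long"
        # 10500 is exonic in the short transcript but intronic in the longest
        label, _ = classify_region(_match(10_500, 10_520), gene)
        assert label == "intron"


class TestStrandConcordance:
    def test_plus_gene_concordant_minus_not(self):
        m = _match(10_500, 10_520)
        assert strand_concordant(m, _simple_gene(strand="+"))
        assert not strand_concordant(m, _simple_gene(strand="-"))

    def test_random_strands_give_half_concordance(self):
        rng = np.random.default_rng(12)
        n = 2_000
        genes = []
        for i in range(n):
            g = _simple_gene(10_000 + 40_000 * i, 12_000 + 40_000 * i,
                             "+" if rng.random() < 0.5 else "-")
            g.gene_id = g.symbol = f"g{i}"
            genes.append(g)
        matches = [_match(g.start + 100, g.start + 120) for g in genes]
        anns = associate_genes(matches, genes)
        frac = np.mean([a.strand_concordant for a in anns])
        sigma = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 3 * sigma


class TestRepeatOverlap:
    def test_one_bp_intersection_counts(self):
        m = _match(100, 130)
        flags = repeat_overlap([m], [RepeatFeature("chr1", 120, 200, "DNA")])
        assert flags[m.key] == (True, ("DNA",))

    def test_half_open_touching_is_no_overlap(self):
        m = _match(100, 130)
        flags = repeat_overlap([m], [RepeatFeature("chr1", 130, 200, "DNA")])
        assert flags[m.key][0] is False

    def test_random_matches_hit_covered_fraction(self):
        rng = np.random.default_rng(5)
        L, cover = 1_000_000, 0.4
        repeats = [
            RepeatFeature("chr1", s, s + 400, "fam")
            for s in range(0, L, 1_000)  # 40% tiling
        ]
        matches = [
            _match(int(p), int(p) + 20) for p in rng.integers(0, L - 20, size=2_000)
        ]
        flags = repeat_overlap(matches, repeats)
        frac = np.mean([flags[m.key][0] for m in matches])
        sigma = np.sqrt(cover * (1 - cover) / len(matches))
        assert abs(frac - cover) < 3 * sigma + 20 / 1_000  # edge slack: motif width

    def test_repeatmasker_out_format(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW   perc perc perc  query      position in query\n"
            "score   div. del. ins.  sequence     begin    end\n"
            "\n"
            "  463   12.4  0.0  0.0  chr1        101      200 (0) +  "
            "TE-X-4_DR  DNA/hAT-Ac   1  100  (0)   1\n"
        )
        reps = load_repeats(p)
        assert len(reps) == 1
        assert (reps[0].chrom, reps[0].start, reps[0].end) == ("chr1", 100, 200)

    def test_bed_format(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t200\thAT-AC\nchr2\t5\t50\tDNA\n")
        reps = load_repeats(p)
        assert [r.family for r in reps] == ["hAT-AC", "DNA"]


class TestSummarize:
    def test_zero_matches_all_zero(self, default_pattern):
        ms = MatchSet(matches=[], pattern=default_pattern, genome_length=1_000)
        stats = summarize([], ms)
        assert stats.n_patterns == 0 and stats.n_gene_related == 0
        assert sum(stats.spacer_histogram.values()) == 0
        assert stats.density_per_mb == 0.0

    def test_genome_scale_density_consistency(self, default_pattern):
        """3,033 patterns over a 1,348 Mb genome average 2.25 per Mb
        (consistency check on the density formula, not ground truth)."""
        matches = [_match(i * 100, i * 100 + 20) for i in range(3_033)]
        ms = MatchSet(matches=matches, pattern=default_pattern,
                      genome_length=1_348_000_000)
        stats = summarize([], ms)
        assert stats.density_per_mb == pytest.approx(2.25, abs=0.005)

    def test_planted_composition_recovered_exactly(self, default_pattern):
        """Scan + annotate + summarize on the hand-built fixture reproduces
        every hand-derived summary field."""
        genome = fx.build_genome()
        ms = scan_genome(genome, default_pattern)
        # the all-T background admits exactly the planted sites
        assert [(m.start, m.spacer) for m in ms] == [
            (s, 0) for s, _ in sorted(fx.PLANTED)
        ]
        anns = associate_genes(ms, fx.build_genes())
        flags = repeat_overlap(ms, fx.build_repeats())
        apply_repeat_overlap(anns, flags)
        stats = summarize(anns, ms, repeat_flags=flags)
        assert stats == fx.EXPECTED_STATS

    def test_bookkeeping_invariants_on_fixture(self, default_pattern):
        genome = fx.build_genome()
        ms = scan_genome(genome, default_pattern)
        anns = associate_genes(ms, fx.build_genes())
        stats = summarize(anns, ms)
        assert (
            stats.n_unique_gene_related + stats.n_multi_gene_patterns
            == stats.n_gene_related
        )
        assert sum(stats.genes_by_biotype.values()) == stats.n_genes
        assert sum(stats.spacer_histogram.values()) == stats.n_patterns
        assert sum(stats.region_counts.values()) == stats.n_patterns_same_orientation

    def test_summary_has_a_field_per_reported_statistic(self):
        """Schema check: every roll-up row has a named SummaryStats field."""
        required = {
            "n_patterns", "n_gene_related", "n_unique_gene_related",
            "n_multi_gene_patterns", "n_genes", "genes_by_biotype",
            "n_genes_multi_pattern", "n_patterns_same_orientation",
            "n_genes_same_orientation", "region_counts",
            "n_gene_related_in_repeats", "n_total_in_repeats",
            "spacer_histogram", "density_per_mb",
        }
        assert required.issubset(SummaryStats.__dataclass_fields__.keys())

    def test_annotations_dataframe_printed_coordinates(self, default_pattern):
        genome = fx.build_genome()
        ms = scan_genome(genome, default_pattern)
        anns = associate_genes(ms, fx.build_genes())
        df = annotations_to_dataframe(anns)
        first = df.iloc[0]
        assert first["start"] == 6_501  # 1-based inclusive
        assert first["end"] == 6_520
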