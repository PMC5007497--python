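"""Hand-built planted-truth fixture with a fully known summary composition.

A 100 kb all-T chromosome (T satisfies no purine position, so the
background can never complete a half-site) carrying 12 planted consensus
sites at hand-chosen positions relative to 5 hand-built genes and 4 repeat
intervals.  Every SummaryStats field is derivable by hand; the expected
values are frozen in ``EXPECTED_STATS``.
"""

from p53re.annotate import GeneModel, RepeatFeature, SummaryStats, TranscriptModel
from p53re.sequence_io import Genome, SequenceRecord

CONSENSUS = "AAACATGTTTAAACATGTTT"  # spacer-0 consensus sample, length 20
CHROM_LEN = 100_000

# (start, role) — 0-based; all sites are spacer 0
PLANTED = [
    (2_000, "intergenic"),
    (6_500, "upstream of gA, in repeat"),
    (10_050, "gA five_prime_UTR"),
    (10_600, "gA intron, in repeat"),
    (25_600, "downstream of gB (minus strand)"),
    (32_000, "gB exon"),
    (47_000, "upstream of gC"),
    (55_500, "gC+gD windows (multi-gene), in repeat"),
    (56_000, "gC+gD windows (multi-gene)"),
    (61_000, "gD exon"),
    (80_500, "gE (miRNA) exon"),
    (95_000, "intergenic, in repeat"),
]


def _gene(gene_id, strand, start, end, exons, utr5=(), utr3=(), biotype="protein_coding"):
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1", strand=strand, start=start, end=end,
        exons=list(exons), five_prime_utr=list(utr5), three_prime_utr=list(utr3),
    )
    return GeneModel(
        gene_id=gene_id, symbol=gene_id, biotype=biotype, chrom="chr1",
        strand=strand, start=start, end=end, transcripts=[tx],
    )


def build_genes() -> list[GeneModel]:
    return [
        _gene("gA", "+", 10_000, 12_000,
              exons=[(10_000, 10_500), (11_000, 12_000)],
              utr5=[(10_000, 10_100)]),
        _gene("gB", "-", 30_000, 33_000,
              exons=[(30_000, 31_000), (32_000, 33_000)],
              utr5=[(32_900, 33_000)]),
        _gene("gC", "+", 50_000, 52_000,
              exons=[(50_000, 50_400), (51_000, 52_000)],
              utr5=[(50_000, 50_100)]),
        _gene("gD", "+", 60_000, 62_000, exons=[(60_000, 62_000)]),
        _gene("gE", "+", 80_000, 82_000, exons=[(80_000, 82_000)],
              biotype="miRNA"),
    ]


def build_repeats() -> list[RepeatFeature]:
    return [
        RepeatFeature("chr1", 6_490, 6_530, "hAT-AC"),    # covers site at 6500
        RepeatFeature("chr1", 10_590, 10_610, "DNA"),     # partial over 10600
        RepeatFeature("chr1", 55_490, 55_505, "TE-X-4_DR"),  # partial over 55500
        RepeatFeature("chr1", 94_990, 95_100, "hAT-AC"),  # covers 95000 (intergenic)
    ]


def build_genome() -> Genome:
    seq = ["T"] * CHROM_LEN
    for start, _ in PLANTED:
        seq[start : start + len(CONSENSUS)] = CONSENSUS
    return Genome(records=[SequenceRecord("chr1", "".join(seq))])


# Every field derived by hand from the layout above:
# 12 patterns, 10 gene-related (2 intergenic), 2 of those near two genes,
# 5 genes hit (4 protein-coding + 1 miRNA), 4 genes with >1 pattern
# (gA:3, gB:2, gC:3, gD:3), 8 patterns concordant with a '+' gene,
# 4 genes on '+', regions of the concordant patterns:
# 1 five_prime_UTR (10050), 4 upstream (6500, 47000, 55500, 56000 — the two
# multi-gene sites are nearest gD's TSS), 1 intron (10600), 2 other
# (exonic 61000 and 80500); repeats: 4 of all 12, 3 of the 10 gene-related.
EXPECTED_STATS = SummaryStats(
    n_patterns=12,
    n_gene_related=10,
    n_unique_gene_related=8,
    n_multi_gene_patterns=2,
    n_genes=5,
    genes_by_biotype={"protein_coding": 4, "miRNA": 1},
    n_genes_multi_pattern=4,
    n_patterns_same_orientation=8,
    n_genes_same_orientation=4,
    region_counts={"five_prime_UTR": 1, "upstream": 4, "intron": 1, "other": 2},
    n_gene_related_in_repeats=3,
    n_total_in_repeats=4,
    spacer_histogram={0: 12, **{s: 0 for s in range(1, 16)}},
    density_per_mb=120.0,
)
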