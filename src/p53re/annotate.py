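"""Gene-context annotation of motif matches and the summary roll-up.

A match is *gene-related* when its interval overlaps the +/-5 kb
neighbourhood of an annotated gene (window anchored on the whole gene span,
not the TSS, so deep intronic hits are kept).  Each (match, gene) pair gets
a region label, a signed TSS distance, a strand-concordance flag and repeat
overlap, and the whole match set rolls up into :class:`SummaryStats`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .pattern import MatchSet, MotifMatch

__all__ = [
    "GeneModel",
    "TranscriptModel",
    "RepeatFeature",
    "PatternAnnotation",
    "SummaryStats",
    "load_annotation",
    "load_repeats",
    "associate_genes",
    "classify_region",
    "strand_concordant",
    "repeat_overlap",
    "summarize",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 5000

REGION_LABELS = (
    "five_prime_UTR",
    "exon",
    "intron",
    "upstream",
    "downstream",
    "three_prime_UTR",
    "intergenic",
)


@dataclass
class TranscriptModel:
    """One transcript: exons/UTRs/CDS as 0-based half-open intervals."""

    transcript_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    three_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def representative_transcript(self) -> TranscriptModel:
        """Longest transcript; ties broken by lexicographically smallest id."""
        if not self.transcripts:
            return TranscriptModel("_span", self.strand, self.start, self.end)
        return min(self.transcripts, key=lambda t: (-t.length, t.transcript_id))


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat / transposable-element interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    family: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat interval must have end > start")


@dataclass
class PatternAnnotation:
    """One (match, gene) association with its genomic context."""

    match: MotifMatch
    gene_id: str
    gene_symbol: str
    gene_strand: str
    biotype: str
    region_label: str
    distance_to_tss: int
    strand_concordant: bool
    repeat_overlap: bool = False
    repeat_families: tuple[str, ...] = ()
    n_genes_for_pattern: int = 1
    n_patterns_for_gene: int = 1


def load_annotation(path) -> list[GeneModel]:
    """Load gene models from a GFF3/GTF file (gene -> transcript -> features).

    Orphan child features are skipped with a warning; biotype is read from
    the ``biotype``/``gene_biotype`` attribute (default ``protein_coding``).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (
            g.attributes.get("biotype", g.attributes.get("gene_biotype", ["protein_coding"]))
        )[0]
        symbol = g.attributes.get("Name", g.attributes.get("gene_name", [g.id]))[0]
        gene = GeneModel(
            gene_id=g.id,
            symbol=symbol,
            biotype=biotype,
            chrom=g.seqid,
            strand=g.strand,
            start=g.start - 1,
            end=g.end,
        )
        for t in db.children(g, level=1):
            if t.featuretype not in ("mRNA", "transcript", "miRNA", "ncRNA"):
                continue
            tx = TranscriptModel(
                transcript_id=t.id, strand=t.strand, start=t.start - 1, end=t.end
            )
            for c in db.children(t, level=1):
                iv = (c.start - 1, c.end)
                if c.featuretype == "exon":
                    tx.exons.append(iv)
                elif c.featuretype == "five_prime_UTR":
                    tx.five_prime_utr.append(iv)
                elif c.featuretype == "three_prime_UTR":
                    tx.three_prime_utr.append(iv)
                elif c.featuretype == "CDS":
                    tx.cds.append(iv)
            tx.exons.sort()
            gene.transcripts.append(tx)
        if not gene.transcripts:
            warnings.warn(f"gene {g.id} has no transcripts; using its span")
        genes.append(gene)
    return genes


def load_repeats(path) -> list[RepeatFeature]:
    """Read repeat intervals from BED or RepeatMasker ``.out`` format.

    RepeatMasker files are recognised by their two header lines ("SW" /
    "score"); columns 5-7 are chrom/start/end (1-based) and column 11 the
    repeat class/family.
    """
    repeats: list[RepeatFeature] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    is_rm = bool(lines) and lines[0].split()[:2] in (["SW", "perc"], ["SW", "score"])
    if is_rm:
        for ln in lines:
            parts = ln.split()
            if parts[0] in ("SW", "score") or not parts[0].isdigit():
                continue
            chrom, start, end = parts[4], int(parts[5]) - 1, int(parts[6])
            family = parts[10] if len(parts) > 10 else "."
            repeats.append(RepeatFeature(chrom, start, end, family))
    else:
        for ln in lines:
            if ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            family = parts[3] if len(parts) > 3 else "."
            repeats.append(RepeatFeature(chrom, start, end, family))
    return repeats


def _signed_tss_distance(match: MotifMatch, tss: int, strand: str) -> int:
    """Distance from the match edge nearest the TSS, signed on the gene
    strand (negative = upstream of the TSS)."""
    if match.start <= tss < match.end:
        return 0
    edges = (match.start, match.end - 1)
    if strand == "+":
        dists = [e - tss for e in edges]
    else:
        dists = [tss - e for e in edges]
    return min(dists, key=abs)


def strand_concordant(match: MotifMatch, gene: GeneModel) -> bool:
    """True iff the gene lies on the scan strand ('+', the fixed convention)."""
    return gene.strand == match.strand


def classify_region(
    match: MotifMatch, gene: GeneModel, window: int = DEFAULT_WINDOW
) -> tuple[str, int]:
    """Region label and signed TSS distance for an associated (match, gene).

    Label precedence when the match touches several feature classes of the
    representative (longest) transcript:
    five_prime_UTR > exon > intron > upstream > downstream > three_prime_UTR.
    """
    tx = gene.representative_transcript
    ms, me = match.start, match.end
    dist = _signed_tss_distance(match, tx.tss, gene.strand)

    def hits(intervals):
        return any(ms < e and me > s for s, e in intervals)

    if hits(tx.five_prime_utr):
        return "five_prime_UTR", dist
    if hits(tx.exons):
        return "exon", dist
    if ms < tx.end and me > tx.start:
        return "intron", dist
    if dist < 0:
        return ("upstream" if -dist <= window else "intergenic"), dist
    if hits(tx.three_prime_utr):
        return "three_prime_UTR", dist
    return "downstream", dist


def associate_genes(
    matches: MatchSet | list[MotifMatch],
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[PatternAnnotation]:
    """All (match, gene) pairs where the match overlaps the gene span +/- window.

    A match inside several gene windows yields several annotations; the
    multiplicity counters (genes per pattern, patterns per gene) are filled
    on every annotation afterwards.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(genes):
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start - window, gene.end + window, idx
        )

    annotations: list[PatternAnnotation] = []
    for m in matches:
        tree = trees.get(m.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(m.start, m.end), key=lambda iv: iv.data):
            gene = genes[iv.data]
            label, dist = classify_region(m, gene, window=window)
            annotations.append(
                PatternAnnotation(
                    match=m,
                    gene_id=gene.gene_id,
                    gene_symbol=gene.symbol,
                    gene_strand=gene.strand,
                    biotype=gene.biotype,
                    region_label=label,
                    distance_to_tss=dist,
                    strand_concordant=strand_concordant(m, gene),
                )
            )

    genes_per_pattern: dict[tuple, set] = {}
    patterns_per_gene: dict[str, set] = {}
    for a in annotations:
        genes_per_pattern.setdefault(a.match.key, set()).add(a.gene_id)
        patterns_per_gene.setdefault(a.gene_id, set()).add(a.match.key)
    for a in annotations:
        a.n_genes_for_pattern = len(genes_per_pattern[a.match.key])
        a.n_patterns_for_gene = len(patterns_per_gene[a.gene_id])
    return annotations


def repeat_overlap(
    matches: MatchSet | list[MotifMatch], repeats: list[RepeatFeature]
) -> dict[tuple, tuple[bool, tuple[str, ...]]]:
    """Per-match overlap flag (>=1 bp intersection; partial overlap counts)
    plus the families of every intersecting repeat."""
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep.family)
    out = {}
    for m in matches:
        tree = trees.get(m.chrom)
        fams: tuple[str, ...] = ()
        if tree is not None:
            fams = tuple(sorted({iv.data for iv in tree.overlap(m.start, m.end)}))
        out[m.key] = (bool(fams), fams)
    return out


def apply_repeat_overlap(
    annotations: list[PatternAnnotation],
    flags: dict[tuple, tuple[bool, tuple[str, ...]]],
) -> None:
    for a in annotations:
        hit, fams = flags.get(a.match.key, (False, ()))
        a.repeat_overlap = hit
        a.repeat_families = fams


@dataclass
class SummaryStats:
    """Table-style roll-up of one scan + annotation pass."""

    n_patterns: int
    n_gene_related: int
    n_unique_gene_related: int
    n_multi_gene_patterns: int
    n_genes: int
    genes_by_biotype: dict[str, int]
    n_genes_multi_pattern: int
    n_patterns_same_orientation: int
    n_genes_same_orientation: int
    region_counts: dict[str, int]
    n_gene_related_in_repeats: int
    n_total_in_repeats: int
    spacer_histogram: dict[int, int]
    density_per_mb: float

    def to_text(self) -> str:
        lines = [
            "General features of the scanned patterns",
            f"Number of patterns\t{self.n_patterns}",
            f"Number of gene-related patterns\t{self.n_gene_related}",
            f"Number of unique gene-related patterns\t{self.n_unique_gene_related}",
            f"Patterns proximal to more than one gene\t{self.n_multi_gene_patterns}",
            "Genes (grouped by biotype)\t"
            + ", ".join(f"{v} {k}" for k, v in sorted(self.genes_by_biotype.items())),
            f"Number of genes\t{self.n_genes}",
            f"Genes with more than one associated pattern\t{self.n_genes_multi_pattern}",
            "Number of patterns in the same orientation of genes"
            f"\t{self.n_patterns_same_orientation}",
            "Number of genes in the same orientation of patterns"
            f"\t{self.n_genes_same_orientation}",
        ]
        for label in ("five_prime_UTR", "upstream", "intron", "other"):
            lines.append(
                f"Proportion of patterns in {label}\t"
                f"{self.region_counts.get(label, 0)}/{self.n_patterns_same_orientation}"
            )
        lines += [
            "Proportion of gene-related patterns within repeats\t"
            f"{self.n_gene_related_in_repeats}/{self.n_gene_related}",
            f"Patterns within repeats (all)\t{self.n_total_in_repeats}/{self.n_patterns}",
            f"Density per Mb\t{self.density_per_mb:.4g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        rows = []
        for key, val in self.__dict__.items():
            if isinstance(val, dict):
                for k, v in sorted(val.items()):
                    rows.append((f"{key}.{k}", v))
            else:
                rows.append((key, val))
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            path, sep="\t", index=False
        )


def summarize(
    annotations: list[PatternAnnotation],
    matches: MatchSet,
    genome_length: int | None = None,
    repeat_flags: dict[tuple, tuple[bool, tuple[str, ...]]] | None = None,
) -> SummaryStats:
    """Compute the full summary from one annotation pass.

    For the per-region breakdown, each pattern concordant with at least one
    gene contributes once, via its concordant annotation with the smallest
    absolute TSS distance (ties: smallest gene_id); labels other than
    5'UTR/upstream/intron are rolled into "other", so the four region counts
    sum to the number of same-orientation patterns.
    """
    genome_length = genome_length if genome_length is not None else matches.genome_length

    genes_per_pattern: dict[tuple, set] = {}
    patterns_per_gene: dict[str, set] = {}
    gene_info: dict[str, tuple[str, str]] = {}  # gene_id -> (biotype, strand)
    concordant_by_pattern: dict[tuple, list[PatternAnnotation]] = {}
    for a in annotations:
        genes_per_pattern.setdefault(a.match.key, set()).add(a.gene_id)
        patterns_per_gene.setdefault(a.gene_id, set()).add(a.match.key)
        gene_info[a.gene_id] = (a.biotype, a.gene_strand)
        if a.strand_concordant:
            concordant_by_pattern.setdefault(a.match.key, []).append(a)

    n_patterns = len(matches)
    n_gene_related = len(genes_per_pattern)
    n_multi = sum(1 for gs in genes_per_pattern.values() if len(gs) > 1)
    n_unique = n_gene_related - n_multi
    n_genes = len(patterns_per_gene)
    genes_by_biotype: dict[str, int] = {}
    for gid, (biotype, _) in gene_info.items():
        genes_by_biotype[biotype] = genes_by_biotype.get(biotype, 0) + 1
    n_genes_multi = sum(1 for ms in patterns_per_gene.values() if len(ms) > 1)
    n_genes_same = sum(1 for _, (_, strand) in gene_info.items() if strand == "+")

    region_counts = {"five_prime_UTR": 0, "upstream": 0, "intron": 0, "other": 0}
    for key, anns in concordant_by_pattern.items():
        best = min(anns, key=lambda a: (abs(a.distance_to_tss), a.gene_id))
        label = best.region_label
        if label not in ("five_prime_UTR", "upstream", "intron"):
            label = "other"
        region_counts[label] += 1
    n_same_orientation = len(concordant_by_pattern)

    n_total_in_repeats = 0
    n_gene_related_in_repeats = 0
    if repeat_flags:
        for m in matches:
            hit, _ = repeat_flags.get(m.key, (False, ()))
            if hit:
                n_total_in_repeats += 1
                if m.key in genes_per_pattern:
                    n_gene_related_in_repeats += 1

    return SummaryStats(
        n_patterns=n_patterns,
        n_gene_related=n_gene_related,
        n_unique_gene_related=n_unique,
        n_multi_gene_patterns=n_multi,
        n_genes=n_genes,
        genes_by_biotype=genes_by_biotype,
        n_genes_multi_pattern=n_genes_multi,
        n_patterns_same_orientation=n_same_orientation,
        n_genes_same_orientation=n_genes_same,
        region_counts=region_counts,
        n_gene_related_in_repeats=n_gene_related_in_repeats,
        n_total_in_repeats=n_total_in_repeats,
        spacer_histogram=matches.spacer_histogram,
        density_per_mb=n_patterns / (genome_length / 1e6) if genome_length else 0.0,
    )


def annotations_to_dataframe(annotations: list[PatternAnnotation]) -> pd.DataFrame:
    """One row per (pattern, gene) pair, 1-based printed coordinates.

    Note: pattern strand is always '+' by the forward-scan convention, so
    strand concordance reduces to the gene lying on '+'.
    """
    return pd.DataFrame(
        {
            "chrom": [a.match.chrom for a in annotations],
            "start": [a.match.start + 1 for a in annotations],
            "end": [a.match.end for a in annotations],
            "spacer": [a.match.spacer for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "gene_symbol": [a.gene_symbol for a in annotations],
            "biotype": [a.biotype for a in annotations],
            "gene_strand": [a.gene_strand for a in annotations],
            "region": [a.region_label for a in annotations],
            "distance_to_tss": [a.distance_to_tss for a in annotations],
            "strand_concordant": [a.strand_concordant for a in annotations],
            "repeat_overlap": [a.repeat_overlap for a in annotations],
            "repeat_families": [
                ",".join(a.repeat_families) for a in annotations
            ],
            "genes_for_pattern": [a.n_genes_for_pattern for a in annotations],
            "patterns_for_gene": [a.n_patterns_for_gene for a in annotations],
        }
    )
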