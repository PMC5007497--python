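"""Synthetic genomes, gene models, repeats and planted motifs with known truth.

The generator emulates the inputs of a genome-wide response-element scan —
a multi-chromosome background genome with configurable base frequencies,
planted bipartite motif instances with a chosen spacer distribution, toy
gene models with exon/UTR structure, and repeat intervals — so the whole
pipeline is testable at desk scale against planted ground truth.  All
randomness flows from a single integer seed; outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .annotate import GeneModel, RepeatFeature, TranscriptModel
from .pattern import (
    DEFAULT_PATTERN_SPEC,
    IUPACPattern,
    MotifMatch,
    compile_pattern,
)
from .pwm import Background, PWMPair
from .sequence_io import IUPAC_TABLE, Genome, SequenceRecord

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "gen_genome",
    "sample_from_pattern",
    "sample_from_pwm_pair",
    "expected_match_count",
    "gen_gene_models",
    "gen_repeats",
    "write_gff3",
    "write_truth_bed",
    "write_manifest",
]

_BASES = "ACGT"


def _uniform_spacer_distribution(spacer_min: int = 0, spacer_max: int = 15):
    n = spacer_max - spacer_min + 1
    return {s: 1.0 / n for s in range(spacer_min, spacer_max + 1)}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic fixture.

    Defaults describe the standard desk-scale fixture: one 1 Mb chromosome
    of i.i.d. uniform background with 25 planted consensus-sampled sites,
    a uniform 0-15 bp spacer distribution, 50 genes and 40% repeat cover.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    background: Background = field(default_factory=Background.uniform)
    n_planted: int = 25
    spacer_distribution: dict[int, float] = field(
        default_factory=_uniform_spacer_distribution
    )
    planting_source: str = "consensus_sample"  # or "pwm_sample"
    n_genes: int = 50
    gene_length_min: int = 2_000
    gene_length_max: int = 8_000
    repeat_fraction: float = 0.4
    pattern_spec: str = DEFAULT_PATTERN_SPEC

    def __post_init__(self) -> None:
        probs = np.array(list(self.spacer_distribution.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("spacer distribution must be a probability vector")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0,1]")
        if self.planting_source not in ("consensus_sample", "pwm_sample"):
            raise ValueError(f"unknown planting source {self.planting_source!r}")

    @property
    def pattern(self) -> IUPACPattern:
        return compile_pattern(self.pattern_spec)


@dataclass
class TruthSet:
    """Planted ground truth accompanying a synthetic fixture."""

    planted: list[MotifMatch] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)


def sample_from_pattern(
    pattern: IUPACPattern, spacer: int, rng: np.random.Generator
) -> str:
    """Sample one concrete site: each degenerate symbol resolved uniformly
    over its base set, spacer bases uniform over A/C/G/T."""
    if not pattern.spacer_min <= spacer <= pattern.spacer_max:
        raise ValueError(f"spacer {spacer} outside pattern bounds")
    out = []
    for sym in pattern.half1:
        choices = sorted(IUPAC_TABLE[sym.upper()])
        out.append(choices[rng.integers(len(choices))])
    for _ in range(spacer):
        out.append(_BASES[rng.integers(4)])
    for sym in pattern.half2:
        choices = sorted(IUPAC_TABLE[sym.upper()])
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def sample_from_pwm_pair(
    pair: PWMPair, spacer: int, rng: np.random.Generator
) -> str:
    """Sample a full site from the empirical column frequencies of a PWM pair.

    Sampling uses the observed (count-based) frequencies, not the
    pseudocounted scoring frequencies: the pseudocount regularizes scoring
    and is not part of the generative truth, so bases unseen in the
    training sites are never planted.
    """
    out = []
    for pwm in (pair.left, pair.right):
        probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
        for pos in range(pwm.width):
            out.append(_BASES[rng.choice(4, p=probs[pos])])
        if pwm is pair.left:
            out.extend(_BASES[i] for i in rng.integers(0, 4, size=spacer))
    return "".join(out)


def _random_background(
    length: int, background: Background, rng: np.random.Generator
) -> np.ndarray:
    codes = rng.choice(4, size=length, p=background.array)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes]


def gen_genome(
    config: SimulationConfig,
    pwm_pair: PWMPair | None = None,
    max_retries: int = 200,
) -> tuple[Genome, TruthSet]:
    """Generate the background genome with planted, non-overlapping sites.

    Planted sites avoid each other and the chromosome edges by the maximal
    site length, which keeps the truth bookkeeping trivially exact.  Raises
    if the requested planting density cannot be placed within bounded
    retries.
    """
    rng = np.random.default_rng(config.seed)
    pattern = config.pattern
    margin = pattern.max_length
    spacers = sorted(config.spacer_distribution)
    spacer_probs = np.array([config.spacer_distribution[s] for s in spacers])

    arrays = [
        _random_background(config.chrom_length, config.background, rng)
        for _ in range(config.n_chroms)
    ]
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    truth = TruthSet()
    placed: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.n_chroms)}
    for _ in range(config.n_planted):
        spacer = int(spacers[rng.choice(len(spacers), p=spacer_probs)])
        if config.planting_source == "pwm_sample":
            if pwm_pair is None:
                raise ValueError("pwm_sample planting requires a PWMPair")
            site = sample_from_pwm_pair(pwm_pair, spacer, rng)
        else:
            site = sample_from_pattern(pattern, spacer, rng)
        for attempt in range(max_retries):
            ci = int(rng.integers(config.n_chroms))
            pos = int(rng.integers(margin, config.chrom_length - margin - len(site)))
            ok = all(
                pos + len(site) + margin <= s or pos >= e + margin
                for s, e in placed[ci]
            )
            if ok:
                break
        else:
            raise RuntimeError(
                "could not place planted site without overlap; "
                "lower n_planted or enlarge the genome"
            )
        placed[ci].append((pos, pos + len(site)))
        arrays[ci][pos : pos + len(site)] = np.frombuffer(
            site.encode("ascii"), dtype=np.uint8
        )
        truth.planted.append(
            MotifMatch(
                chrom=names[ci],
                start=pos,
                end=pos + len(site),
                spacer=spacer,
                strand="+",
                sequence=site,
            )
        )

    truth.planted.sort(key=lambda m: (m.chrom, m.start, m.end))
    genome = Genome(
        records=[
            SequenceRecord(id=name, seq=arr.tobytes().decode("ascii"))
            for name, arr in zip(names, arrays)
        ]
    )
    return genome, truth


def expected_match_count(
    length: int, background: Background, pattern: IUPACPattern
) -> float:
    """Analytic expectation of the match count on an i.i.d. background
    sequence of the given length (edge effects handled exactly)."""
    def half_prob(half: str) -> float:
        p = 1.0
        for sym in half:
            p *= sum(background[b] for b in IUPAC_TABLE[sym.upper()])
        return p

    p_site = half_prob(pattern.half1) * half_prob(pattern.half2)
    total = 0.0
    for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
        n_pos = length - (pattern.h1 + spacer + pattern.h2) + 1
        if n_pos > 0:
            total += n_pos * p_site
    return total


def gen_gene_models(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mirna_fraction: float = 0.1,
) -> list[GeneModel]:
    """Non-overlapping toy genes: random strand, one transcript, 2-8 exons,
    a 5'UTR on the first and a 3'UTR on the last exon (protein-coding genes);
    a configurable fraction are single-exon miRNA genes."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        # adaptive stride so the requested gene count fits the chromosome
        usable = config.chrom_length - 20_000
        stride = usable / n_here
        if stride < config.gene_length_max + 500:
            raise ValueError(
                f"chromosome of {config.chrom_length} bp cannot hold "
                f"{n_here} non-overlapping genes"
            )
        cursor = 10_000
        for _ in range(n_here):
            glen = int(
                rng.integers(config.gene_length_min, config.gene_length_max + 1)
            )
            max_jitter = max(1, int(0.2 * (stride - glen)))
            gap = int(stride - glen) + int(rng.integers(-max_jitter, max_jitter + 1))
            gap = max(500, gap)
            start = cursor
            end = start + glen
            cursor = end + gap
            if end + 1_000 > config.chrom_length:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            is_mirna = rng.random() < mirna_fraction
            gene_id = f"gene{gid:04d}"
            tx = TranscriptModel(
                transcript_id=f"tx{gid:04d}", strand=strand, start=start, end=end
            )
            if is_mirna:
                tx.exons = [(start, end)]
                biotype = "miRNA"
            else:
                biotype = "protein_coding"
                n_exons = int(rng.integers(2, 9))
                for _ in range(50):
                    cuts = np.sort(
                        rng.choice(
                            np.arange(start + 1, end - 1),
                            size=2 * (n_exons - 1),
                            replace=False,
                        )
                    )
                    bounds = [start, *cuts.tolist(), end]
                    segs = [
                        (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)
                    ]
                    if all(e - s >= 50 for s, e in segs):
                        break
                tx.exons = segs
                first = tx.exons[0] if strand == "+" else tx.exons[-1]
                last = tx.exons[-1] if strand == "+" else tx.exons[0]
                utr5 = min(100, (first[1] - first[0]) // 2)
                utr3 = min(100, (last[1] - last[0]) // 2)
                if strand == "+":
                    tx.five_prime_utr = [(first[0], first[0] + utr5)]
                    tx.three_prime_utr = [(last[1] - utr3, last[1])]
                else:
                    tx.five_prime_utr = [(first[1] - utr5, first[1])]
                    tx.three_prime_utr = [(last[0], last[0] + utr3)]
                tx.cds = _subtract_utrs(tx.exons, tx.five_prime_utr + tx.three_prime_utr)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id,
                    biotype=biotype,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    transcripts=[tx],
                )
            )
    return genes


def _subtract_utrs(exons, utrs):
    out = []
    for s, e in exons:
        segs = [(s, e)]
        for us, ue in utrs:
            segs = [
                piece
                for a, b in segs
                for piece in ((a, min(b, us)), (max(a, ue), b))
                if piece[1] > piece[0]
            ]
        out.extend(segs)
    return sorted(out)


def gen_repeats(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[RepeatFeature]:
    """Tile each chromosome with non-overlapping repeat intervals whose
    total cover approximates ``repeat_fraction``; family labels only, no
    repeat sequence model."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if config.repeat_fraction <= 0:
        return []
    families = ["hAT-AC", "DNA", "TE-X-4_DR", "LINE", "LTR"]
    fam_probs = np.array([0.30, 0.14, 0.14, 0.22, 0.20])
    rep_mean = 1_000
    gap_mean = max(1.0, rep_mean * (1 - config.repeat_fraction) / config.repeat_fraction)
    repeats: list[RepeatFeature] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.exponential(gap_mean))
        while cursor < config.chrom_length - 200:
            length = int(rng.integers(200, 2 * rep_mean - 200))
            end = min(cursor + length, config.chrom_length)
            family = families[rng.choice(len(families), p=fam_probs)]
            repeats.append(RepeatFeature(chrom, cursor, end, family))
            cursor = end + 1 + int(rng.exponential(gap_mean))
    return repeats


def write_gff3(genes: list[GeneModel], path) -> None:
    """Serialize gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.symbol};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                ftype = "mRNA" if g.biotype == "protein_coding" else "transcript"
                fh.write(
                    f"{g.chrom}\tsim\t{ftype}\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{g.strand}\t.\tID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                feature_sets = [
                    ("exon", tx.exons),
                    ("five_prime_UTR", tx.five_prime_utr),
                    ("three_prime_UTR", tx.three_prime_utr),
                    ("CDS", tx.cds),
                ]
                for ftype2, ivs in feature_sets:
                    for j, (s, e) in enumerate(ivs):
                        fh.write(
                            f"{g.chrom}\tsim\t{ftype2}\t{s + 1}\t{e}\t.\t{g.strand}\t"
                            f"{'0' if ftype2 == 'CDS' else '.'}\t"
                            f"ID={tx.transcript_id}.{ftype2}.{j + 1};"
                            f"Parent={tx.transcript_id}\n"
                        )


def write_truth_bed(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# planted sites; score column holds the spacer length\n")
        for i, m in enumerate(truth.planted):
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\tplanted_{i + 1}\t{m.spacer}\t"
                f"{m.strand}\t{m.sequence}\n"
            )


def write_repeats_bed(repeats: list[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\n")


def write_manifest(config: SimulationConfig, files: dict[str, str], path) -> None:
    """JSON manifest of the config plus sha256 checksums of the outputs."""
    manifest = {
        "config": {
            k: (v if not isinstance(v, Background) else list(v.freqs))
            for k, v in config.__dict__.items()
        },
        "checksums": {},
    }
    for name, fpath in files.items():
        with open(fpath, "rb") as fh:
            manifest["checksums"][name] = hashlib.sha256(fh.read()).hexdigest()
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
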