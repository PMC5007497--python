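"""Exact degenerate scanning of a bipartite motif with a variable spacer.

The canonical p53 response element is two decameric half-sites RRRCWWGYYY
separated by an unconstrained 0-15 bp spacer, written as the pattern string
``RRRCWWGYYYN{0,15}RRRCWWGYYY``.  Scanning is forward-strand only: the
half-site is self-reverse-complementary as a degenerate class and the spacer
is unconstrained, so a minus-strand scan would report the same sites again
at mirrored coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import IUPAC_TABLE, Genome, encode_sequence, symbol_lut

__all__ = [
    "DEFAULT_PATTERN_SPEC",
    "IUPACPattern",
    "MotifMatch",
    "MatchSet",
    "compile_pattern",
    "scan_sequence",
    "scan_genome",
    "infer_spacer",
]

DEFAULT_PATTERN_SPEC = "RRRCWWGYYYN{0,15}RRRCWWGYYY"

_SPACER_RE = re.compile(r"^([A-Za-z]+)N\{\s*(\d+)\s*,\s*(\d+)\s*\}([A-Za-z]+)$")


@dataclass(frozen=True)
class IUPACPattern:
    """Compiled bipartite degenerate motif: two half-sites + spacer range."""

    half1: str
    half2: str
    spacer_min: int
    spacer_max: int
    source_spec: str = ""

    def __post_init__(self) -> None:
        if not self.half1:
            raise ValueError("first half-site must be non-empty")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError(
                f"invalid spacer range {self.spacer_min}..{self.spacer_max}"
            )
        for half in (self.half1, self.half2):
            for ch in half:
                if ch.upper() not in IUPAC_TABLE:
                    raise ValueError(f"non-IUPAC character {ch!r} in pattern")

    @property
    def h1(self) -> int:
        return len(self.half1)

    @property
    def h2(self) -> int:
        return len(self.half2)

    @property
    def min_length(self) -> int:
        return self.h1 + self.spacer_min + self.h2

    @property
    def max_length(self) -> int:
        return self.h1 + self.spacer_max + self.h2


@dataclass(frozen=True)
class MotifMatch:
    """One genomic occurrence of the pattern (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    spacer: int
    strand: str
    sequence: str

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class MatchSet:
    """All matches of one pattern over one genome, sorted and de-duplicated."""

    matches: list[MotifMatch]
    pattern: IUPACPattern
    genome_length: int

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        unique = []
        for m in self.matches:
            if m.key not in seen:
                seen.add(m.key)
                unique.append(m)
        unique.sort(key=lambda m: (m.chrom, m.start, m.end))
        self.matches = unique

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with 1-based inclusive coordinates (printed convention)."""
        return pd.DataFrame(
            {
                "chrom": [m.chrom for m in self.matches],
                "start": [m.start + 1 for m in self.matches],
                "end": [m.end for m in self.matches],
                "spacer": [m.spacer for m in self.matches],
                "strand": [m.strand for m in self.matches],
                "sequence": [m.sequence for m in self.matches],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        """BED6 export, 0-based half-open; the score column carries the spacer."""
        with open(path, "w") as fh:
            fh.write("# BED6; column 5 (score) holds the spacer length in bp\n")
            for i, m in enumerate(self.matches):
                fh.write(
                    f"{m.chrom}\t{m.start}\t{m.end}\tmatch_{i + 1}\t"
                    f"{m.spacer}\t{m.strand}\n"
                )

    @property
    def spacer_histogram(self) -> dict[int, int]:
        hist = {
            s: 0 for s in range(self.pattern.spacer_min, self.pattern.spacer_max + 1)
        }
        for m in self.matches:
            hist[m.spacer] = hist.get(m.spacer, 0) + 1
        return hist


def compile_pattern(spec: str) -> IUPACPattern:
    """Parse ``<half1>N{a,b}<half2>`` (or a plain IUPAC string) into a pattern.

    Whitespace inside the braces is tolerated (``N{0, 15}``).  A plain IUPAC
    string becomes a single block with spacer {0,0} and empty second half.
    """
    spec = spec.strip()
    m = _SPACER_RE.match(spec)
    if m:
        half1, a, b, half2 = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
        if a > b:
            raise ValueError(f"spacer range {{{a},{b}}} has min > max")
        return IUPACPattern(half1, half2, a, b, source_spec=spec)
    if "{" in spec or "}" in spec:
        raise ValueError(f"malformed pattern spec {spec!r}")
    return IUPACPattern(spec, "", 0, 0, source_spec=spec)


def _half_site_mask(codes: np.ndarray, half: str) -> np.ndarray:
    """mask[i] == True iff the half-site is satisfied starting at position i."""
    n = codes.size - len(half) + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for j, sym in enumerate(half):
        mask &= symbol_lut(sym)[codes[j : j + n]]
    return mask


def scan_sequence(
    seq: str,
    pattern: IUPACPattern,
    chrom: str = "seq",
    longest_only: bool = False,
) -> list[MotifMatch]:
    """Report every exact occurrence of the bipartite pattern (forward strand).

    All (start, spacer) combinations are reported: overlapping matches and
    several spacer variants at one start are distinct hits.  With
    ``longest_only`` just the largest-spacer variant per start is kept
    (the alternative collapsed-output convention).
    """
    codes = encode_sequence(seq)
    h1, h2 = pattern.h1, pattern.h2
    m1 = _half_site_mask(codes, pattern.half1)
    if h2 > 0:
        m2 = _half_site_mask(codes, pattern.half2)
    else:
        m2 = None

    out: list[MotifMatch] = []
    for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
        total = h1 + spacer + h2
        n = codes.size - total + 1
        if n <= 0:
            continue
        if m2 is None:
            hits = np.flatnonzero(m1[:n])
        else:
            hits = np.flatnonzero(m1[:n] & m2[h1 + spacer : h1 + spacer + n])
        for start in hits:
            start = int(start)
            out.append(
                MotifMatch(
                    chrom=chrom,
                    start=start,
                    end=start + total,
                    spacer=spacer,
                    strand="+",
                    sequence=seq[start : start + total],
                )
            )
    out.sort(key=lambda m: (m.start, m.end))
    if longest_only:
        best: dict[int, MotifMatch] = {}
        for m in out:
            if m.start not in best or m.end > best[m.start].end:
                best[m.start] = m
        out = sorted(best.values(), key=lambda m: (m.start, m.end))
    return out


def scan_genome(
    genome: Genome, pattern: IUPACPattern, longest_only: bool = False
) -> MatchSet:
    """Scan every record of a genome; deterministic record-order concatenation."""
    matches: list[MotifMatch] = []
    for rec in genome:
        matches.extend(
            scan_sequence(rec.seq, pattern, chrom=rec.id, longest_only=longest_only)
        )
    return MatchSet(matches=matches, pattern=pattern, genome_length=genome.total_length)


def infer_spacer(start: int, end: int, pattern: IUPACPattern) -> int:
    """Spacer length implied by a printed 1-based inclusive interval.

    ``spacer = (end - start + 1) - h1 - h2``; raises if the interval is
    shorter than the two half-sites.
    """
    if end < start:
        raise ValueError("end must be >= start (1-based inclusive)")
    length = end - start + 1
    spacer = length - pattern.h1 - pattern.h2
    if spacer < 0:
        raise ValueError(
            f"interval of length {length} shorter than the half-sites "
            f"({pattern.h1}+{pattern.h2})"
        )
    return spacer
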