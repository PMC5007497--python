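"""Half-site position weight matrices: log-odds scoring, exact p-values, E-values.

The motif model is a pair of 10-position PWMs (one per decamer half-site)
joined by an unconstrained, unscored spacer.  Scores are log2 odds ("bits")
against an i.i.d. background.  P-values are exact up to a stated score
discretization: the full score distribution of a random background word is
obtained by dynamic-programming convolution of the per-position score
distributions, and the pair distribution is the convolution of the two half
distributions (the spacer contributes nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as _bio_motifs

from .pattern import IUPACPattern, MotifMatch
from .sequence_io import Genome, encode_sequence

__all__ = [
    "SENTINEL",
    "Background",
    "HalfSitePWM",
    "PWMPair",
    "ScoredSite",
    "ScoreDistribution",
    "build_pwm",
    "score_site",
    "score_pvalue",
    "site_evalue",
    "pwm_scan",
    "write_meme",
    "read_meme",
]

#: score assigned to a zero-frequency cell when the pseudocount is 0; large
#: negative but finite so sums stay orderable.  A word touching such a cell
#: is "impossible under the model" and ranks below every achievable score.
SENTINEL = -1.0e9

#: any requested threshold at or below this admits impossible words too
#: (p-value 1 by construction).
_SENTINEL_THRESHOLD = -1.0e8

_BASES = "ACGT"


@dataclass(frozen=True)
class Background:
    """i.i.d. (order-0) nucleotide background model."""

    freqs: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        arr = np.asarray(self.freqs, dtype=float)
        if arr.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies (A,C,G,T)")
        if np.any(arr <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {arr.sum()}, not 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def __getitem__(self, base: str) -> float:
        return self.freqs[_BASES.index(base.upper())]

    @classmethod
    def uniform(cls) -> "Background":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Background":
        return cls(tuple(float(d[b]) for b in _BASES))

    @classmethod
    def from_genome(cls, genome: Genome) -> "Background":
        return cls.from_dict(genome.base_frequencies())

    @classmethod
    def from_file(cls, path) -> "Background":
        """Read a 4-line ``A=0.25``-style (or whitespace-separated) text file."""
        vals: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, rest = line.replace("=", " ").partition(" ")
                vals[key.upper()] = float(rest.strip())
        return cls.from_dict(vals)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for base, f in zip(_BASES, self.freqs):
                fh.write(f"{base}={f:.6g}\n")


@dataclass
class ScoreDistribution:
    """Discretized distribution of a PWM score under the background.

    ``probs[i]`` is the probability of integer grid score ``offset + i``
    (units of ``resolution`` bits) over words with no impossible cell;
    ``impossible_mass`` is the probability of touching a sentinel cell.
    """

    offset: int
    probs: np.ndarray
    resolution: float
    impossible_mass: float = 0.0

    def survival(self, score: float) -> float:
        """P(random word scores >= ``score``); impossible words rank below
        every finite threshold."""
        if score <= _SENTINEL_THRESHOLD:
            return 1.0
        k = int(np.ceil(score / self.resolution - 1e-9))
        i = k - self.offset
        if i <= 0:
            return float(self.probs.sum())
        if i >= self.probs.size:
            return 0.0
        return float(self.probs[i:].sum())

    def convolve(self, other: "ScoreDistribution") -> "ScoreDistribution":
        if self.resolution != other.resolution:
            raise ValueError("resolutions differ")
        probs = np.convolve(self.probs, other.probs)
        imp = 1.0 - (1.0 - self.impossible_mass) * (1.0 - other.impossible_mass)
        return ScoreDistribution(
            offset=self.offset + other.offset,
            probs=probs,
            resolution=self.resolution,
            impossible_mass=imp,
        )


class HalfSitePWM:
    """Count/frequency/log-odds matrices for one ungapped half-site.

    ``freqs = (counts + pseudocount) / (row_total + 4*pseudocount)`` per
    position; ``logodds = log2(freqs / background)`` with zero-frequency
    cells pinned at :data:`SENTINEL` when the pseudocount is 0.
    """

    def __init__(
        self,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: Background | None = None,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a (width, 4) array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.background = background or Background.uniform()

        row_tot = counts.sum(axis=1, keepdims=True)
        self.freqs = (counts + pseudocount) / (row_tot + 4.0 * pseudocount)
        bg = self.background.array[None, :]
        with np.errstate(divide="ignore"):
            lo = np.log2(self.freqs / bg)
        lo[self.freqs == 0] = SENTINEL
        self.logodds = lo
        self._dist_cache: dict[tuple, ScoreDistribution] = {}

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def nsites(self) -> float:
        return float(self.counts[0].sum())

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.logodds.argmax(axis=1))

    def score_site(self, word: str) -> float:
        """Log2-odds score of one width-length A/C/G/T word (in bits)."""
        if len(word) != self.width:
            raise ValueError(
                f"word length {len(word)} != PWM width {self.width}"
            )
        total = 0.0
        for pos, ch in enumerate(word.upper()):
            if ch not in _BASES:
                raise ValueError(f"ambiguous base {ch!r} cannot be scored")
            total += self.logodds[pos, _BASES.index(ch)]
        return total

    def score_distribution(
        self, background: Background | None = None, resolution: float = 1e-3
    ) -> ScoreDistribution:
        """Exact background score distribution on a ``resolution``-bit grid."""
        bg = (background or self.background).array
        key = (tuple(bg), resolution)
        if key in self._dist_cache:
            return self._dist_cache[key]
        dist = ScoreDistribution(offset=0, probs=np.array([1.0]), resolution=resolution)
        for pos in range(self.width):
            finite = self.logodds[pos] > _SENTINEL_THRESHOLD
            ks = np.round(self.logodds[pos][finite] / resolution).astype(int)
            ps = bg[finite]
            if ks.size == 0:
                dist = ScoreDistribution(0, np.array([0.0]), resolution, 1.0)
                break
            lo, hi = int(ks.min()), int(ks.max())
            new = np.zeros(dist.probs.size + hi - lo, dtype=float)
            for k, p in zip(ks, ps):
                new[k - lo : k - lo + dist.probs.size] += p * dist.probs
            dist = ScoreDistribution(
                offset=dist.offset + lo, probs=new, resolution=resolution
            )
        dist.impossible_mass = max(0.0, 1.0 - float(dist.probs.sum()))
        self._dist_cache[key] = dist
        return dist

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HalfSitePWM)
            and np.allclose(self.counts, other.counts)
            and self.pseudocount == other.pseudocount
            and np.allclose(self.background.array, other.background.array)
        )


def build_pwm(
    sites: list[str],
    pseudocount: float = 0.25,
    background: Background | None = None,
) -> HalfSitePWM:
    """Build a half-site PWM from equal-length, ungapped A/C/G/T sequences."""
    if not sites:
        raise ValueError("need at least one site to build a PWM")
    width = len(sites[0])
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        if len(site) != width:
            raise ValueError(
                f"site {site!r} has length {len(site)}, expected {width}"
            )
        for pos, ch in enumerate(site.upper()):
            if ch not in _BASES:
                raise ValueError(f"non-ACGT character {ch!r} in site {site!r}")
            counts[pos, _BASES.index(ch)] += 1
    return HalfSitePWM(counts, pseudocount=pseudocount, background=background)


def score_site(pwm: HalfSitePWM, word: str) -> float:
    return pwm.score_site(word)


def score_pvalue(
    pwm: HalfSitePWM,
    background: Background,
    score: float,
    resolution: float = 1e-3,
) -> float:
    """P(random background word of PWM width scores >= ``score``)."""
    return pwm.score_distribution(background, resolution).survival(score)


def site_evalue(pvalue: float, n_candidates: int) -> float:
    """Expected number of equally good hits among ``n_candidates`` scored."""
    if n_candidates < 0:
        raise ValueError("n_candidates must be >= 0")
    return pvalue * n_candidates


@dataclass
class PWMPair:
    """Two half-site PWMs joined by an unconstrained spacer range."""

    left: HalfSitePWM
    right: HalfSitePWM
    spacer_min: int = 0
    spacer_max: int = 15

    def __post_init__(self) -> None:
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("invalid spacer range")

    @property
    def width(self) -> int:
        return self.left.width + self.right.width

    @property
    def max_score(self) -> float:
        return self.left.max_score + self.right.max_score

    @property
    def consensus(self) -> str:
        return self.left.consensus + self.right.consensus

    def score_sequence(self, seq: str) -> float:
        """Combined score of a full site (left half + spacer + right half)."""
        spacer = len(seq) - self.width
        if spacer < 0:
            raise ValueError("sequence shorter than the two half-sites")
        return self.left.score_site(
            seq[: self.left.width]
        ) + self.right.score_site(seq[len(seq) - self.right.width :])

    def pair_distribution(
        self, background: Background, resolution: float = 1e-3
    ) -> ScoreDistribution:
        return self.left.score_distribution(background, resolution).convolve(
            self.right.score_distribution(background, resolution)
        )

    def pvalue(
        self, background: Background, score: float, resolution: float = 1e-3
    ) -> float:
        return self.pair_distribution(background, resolution).survival(score)


@dataclass(frozen=True)
class ScoredSite:
    """A MotifMatch with PWM score (bits), exact p-value, and E-value."""

    chrom: str
    start: int
    end: int
    spacer: int
    strand: str
    sequence: str
    score: float
    pvalue: float
    evalue: float

    def as_match(self) -> MotifMatch:
        return MotifMatch(
            self.chrom, self.start, self.end, self.spacer, self.strand, self.sequence
        )


def _window_scores(codes: np.ndarray, pwm: HalfSitePWM) -> np.ndarray:
    """score[i] of the width-long word starting at i; -inf where any base is N."""
    w = pwm.width
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0)
    lut = np.hstack([pwm.logodds, np.full((w, 1), -np.inf)])  # col 4: N/other
    scores = np.zeros(n)
    for j in range(w):
        scores += lut[j][codes[j : j + n]]
    return scores


def pwm_scan(
    genome: Genome,
    pair: PWMPair,
    background: Background | None = None,
    min_score: float | None = None,
    min_score_frac: float = 0.6,
    resolution: float = 1e-3,
) -> list[ScoredSite]:
    """Scan a genome with a PWM pair over all spacers (forward strand only).

    Every (position, spacer) whose combined half-site score reaches
    ``min_score`` (default: ``min_score_frac`` of the maximum achievable
    score) is reported with its exact p-value from the convolved pair
    distribution and an E-value against the number of candidates scanned.
    """
    if background is None:
        background = Background.from_genome(genome)
    if min_score is None:
        min_score = min_score_frac * pair.max_score
    dist = pair.pair_distribution(background, resolution)

    hits: list[tuple[str, int, int, float]] = []
    n_candidates = 0
    lw, rw = pair.left.width, pair.right.width
    for rec in genome:
        codes = encode_sequence(rec.seq)
        ls = _window_scores(codes, pair.left)
        rs = _window_scores(codes, pair.right)
        for spacer in range(pair.spacer_min, pair.spacer_max + 1):
            total = lw + spacer + rw
            n = codes.size - total + 1
            if n <= 0:
                continue
            n_candidates += n
            combined = ls[:n] + rs[lw + spacer : lw + spacer + n]
            for i in np.flatnonzero(combined >= min_score):
                hits.append((rec.id, int(i), spacer, float(combined[i])))

    out = []
    for chrom, start, spacer, score in hits:
        end = start + lw + spacer + rw
        p = dist.survival(score)
        out.append(
            ScoredSite(
                chrom=chrom,
                start=start,
                end=end,
                spacer=spacer,
                strand="+",
                sequence=genome.fetch(chrom, start, end),
                score=score,
                pvalue=p,
                evalue=site_evalue(p, n_candidates),
            )
        )
    out.sort(key=lambda s: (-s.score, s.chrom, s.start, s.end))
    return out


def scored_sites_to_dataframe(sites: list[ScoredSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start + 1 for s in sites],
            "end": [s.end for s in sites],
            "spacer": [s.spacer for s in sites],
            "strand": [s.strand for s in sites],
            "sequence": [s.sequence for s in sites],
            "score": [s.score for s in sites],
            "pvalue": [s.pvalue for s in sites],
            "evalue": [s.evalue for s in sites],
        }
    )


def write_meme(pair: PWMPair, path, names: tuple[str, str] = ("half1", "half2")) -> None:
    """Write the two half-site PWMs as a MEME minimal motif file."""
    bg = pair.left.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg.freqs)) + "\n\n"
        )
        for name, pwm in zip(names, (pair.left, pair.right)):
            fh.write(f"MOTIF {name}\n")
            nsites = int(round(pwm.nsites)) or 1
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {nsites} E= 0\n"
            )
            probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
            for row in probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(
    path,
    pseudocount: float = 0.25,
    spacer_min: int = 0,
    spacer_max: int = 15,
) -> PWMPair:
    """Read a 2-motif MEME minimal file back into a PWMPair."""
    with open(path) as fh:
        parsed = _bio_motifs.parse(fh, "minimal")
        records = list(parsed)
        bg_raw = {b: parsed.background[b] for b in _BASES}
    tot = sum(bg_raw.values())
    background = Background.from_dict({b: v / tot for b, v in bg_raw.items()})
    if len(records) != 2:
        raise ValueError(f"expected 2 motifs (half-sites), found {len(records)}")
    pwms = []
    for rec in records:
        counts = np.array(
            [[rec.counts[b][i] for b in _BASES] for i in range(rec.length)]
        )
        pwms.append(
            HalfSitePWM(counts, pseudocount=pseudocount, background=background)
        )
    return PWMPair(pwms[0], pwms[1], spacer_min=spacer_min, spacer_max=spacer_max)
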