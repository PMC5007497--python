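"""PWM-seeded similarity re-search over candidate response elements.

Validated sites (each 10 + spacer + 10 bp) are laid out in a fixed frame —
first half-site left-justified, second half-site right-justified, gap
columns in between — and the two gap-free decamer blocks seed a pair of
half-site PWMs.  Candidates are then ranked two ways: by E-value with a
MAST-style cutoff (expected hits in a candidate set of this size) and by
the exact p-value of the best combined score with a matrix-scan-style
alpha; the re-search result is the intersection of the two significant
sets, ordered by E-value rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pwm import (
    Background,
    HalfSitePWM,
    PWMPair,
    build_pwm,
    site_evalue,
)

__all__ = [
    "MotifAlignment",
    "CandidateScore",
    "CandidateRanking",
    "align_res",
    "build_halfsite_pwms",
    "mast_like_rank",
    "matrixscan_like",
    "rank_candidates",
    "consensus_candidates",
    "pwm_robustness",
]

GAP = "-"
DEFAULT_EVALUE_CUTOFF = 10.0
DEFAULT_ALPHA = 0.05


@dataclass
class MotifAlignment:
    """Fixed-frame alignment of bipartite sites with unequal spacers.

    ``frame_width = half widths + max observed spacer``; row *i* carries its
    site's first half at the left edge, second half at the right edge, its
    spacer immediately after the first half, and gap characters filling the
    remainder.  The two half-site blocks are gap-free by construction.
    """

    rows: list[str]
    spacers: list[int]
    half_width: int = 10

    @property
    def frame_width(self) -> int:
        return self.rows[0].__len__() if self.rows else 2 * self.half_width

    def left_block(self) -> list[str]:
        return [r[: self.half_width] for r in self.rows]

    def right_block(self) -> list[str]:
        return [r[-self.half_width :] for r in self.rows]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in enumerate(self.rows):
                fh.write(f">site_{i + 1} spacer={self.spacers[i]}\n{row}\n")


def align_res(
    res: list[tuple[str, int]], half_width: int = 10
) -> MotifAlignment:
    """Deterministic spacer-padding alignment of (sequence, spacer) pairs.

    Each sequence must be ``2*half_width + spacer`` long; the frame is
    ``2*half_width + max(spacer)`` columns wide.
    """
    if not res:
        raise ValueError("need at least one site to align")
    for seq, spacer in res:
        if len(seq) != 2 * half_width + spacer:
            raise ValueError(
                f"site {seq!r} has length {len(seq)}, expected "
                f"{2 * half_width + spacer} for spacer {spacer}"
            )
    max_spacer = max(s for _, s in res)
    frame = 2 * half_width + max_spacer
    rows = []
    for seq, spacer in res:
        left = seq[: half_width + spacer]
        right = seq[half_width + spacer :]
        rows.append(left + GAP * (max_spacer - spacer) + right)
    assert all(len(r) == frame for r in rows)
    return MotifAlignment(rows=rows, spacers=[s for _, s in res], half_width=half_width)


def build_halfsite_pwms(
    aln: MotifAlignment,
    pseudocount: float = 0.25,
    background: Background | None = None,
    spacer_min: int = 0,
    spacer_max: int = 15,
) -> PWMPair:
    """PWM pair from the two gap-free decamer blocks of the alignment."""
    left = build_pwm(aln.left_block(), pseudocount=pseudocount, background=background)
    right = build_pwm(aln.right_block(), pseudocount=pseudocount, background=background)
    return PWMPair(left, right, spacer_min=spacer_min, spacer_max=spacer_max)


@dataclass(frozen=True)
class CandidateScore:
    candidate_id: str
    sequence: str
    score: float
    pvalue: float
    evalue: float


@dataclass
class CandidateRanking:
    """Per-candidate scores plus the two significance sets and their
    intersection (``consensus``)."""

    scores: list[CandidateScore]
    significant_mast: list[str]
    significant_scan: list[str]
    evalue_cutoff: float
    alpha: float

    @property
    def consensus(self) -> list[str]:
        scan = set(self.significant_scan)
        return [cid for cid in self.significant_mast if cid in scan]

    def to_dataframe(self) -> pd.DataFrame:
        mast, scan = set(self.significant_mast), set(self.significant_scan)
        cons = set(self.consensus)
        return pd.DataFrame(
            {
                "candidate_id": [s.candidate_id for s in self.scores],
                "sequence": [s.sequence for s in self.scores],
                "score": [s.score for s in self.scores],
                "pvalue": [s.pvalue for s in self.scores],
                "evalue": [s.evalue for s in self.scores],
                "in_mast": [s.candidate_id in mast for s in self.scores],
                "in_scan": [s.candidate_id in scan for s in self.scores],
                "in_consensus": [s.candidate_id in cons for s in self.scores],
            }
        )


def _score_candidates(
    candidates: list[tuple[str, str]],
    pair: PWMPair,
    background: Background,
    resolution: float = 1e-3,
) -> list[CandidateScore]:
    dist = pair.pair_distribution(background, resolution)
    n = len(candidates)
    out = []
    for cid, seq in candidates:
        score = pair.score_sequence(seq)
        p = dist.survival(score)
        out.append(CandidateScore(cid, seq, score, p, site_evalue(p, n)))
    # MAST convention: ascending E-value, ties broken by candidate id
    out.sort(key=lambda s: (s.evalue, s.candidate_id))
    return out


def mast_like_rank(
    candidates: list[tuple[str, str]],
    pair: PWMPair,
    background: Background,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[CandidateScore]:
    """Candidates with E-value <= cutoff, sorted by ascending E-value."""
    scores = _score_candidates(candidates, pair, background)
    return [s for s in scores if s.evalue <= evalue_cutoff]


def matrixscan_like(
    candidates: list[tuple[str, str]],
    pair: PWMPair,
    background: Background,
    alpha: float = DEFAULT_ALPHA,
) -> list[CandidateScore]:
    """Candidates whose best combined-score p-value is < alpha."""
    scores = _score_candidates(candidates, pair, background)
    return [s for s in scores if s.pvalue < alpha]


def rank_candidates(
    candidates: list[tuple[str, str]],
    pair: PWMPair,
    background: Background,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
) -> CandidateRanking:
    """Score once, apply both significance gates, keep the intersection."""
    scores = _score_candidates(candidates, pair, background)
    return CandidateRanking(
        scores=scores,
        significant_mast=[s.candidate_id for s in scores if s.evalue <= evalue_cutoff],
        significant_scan=[s.candidate_id for s in scores if s.pvalue < alpha],
        evalue_cutoff=evalue_cutoff,
        alpha=alpha,
    )


def consensus_candidates(ranking: CandidateRanking) -> list[str]:
    """Intersection of the two significant sets, ordered by E-value rank."""
    return ranking.consensus


def pwm_robustness(
    candidates: list[tuple[str, str]],
    seed_sets: list[list[tuple[str, int]]],
    background: Background,
    pseudocount: float = 0.25,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Re-run the consensus search with PWMs rebuilt from alternative seed
    RE sets and report, per seed set and per method, the overlap with the
    first (reference) seed set's selections."""
    if len(seed_sets) < 2:
        raise ValueError("need at least two seed sets to compare")
    rankings = []
    for seeds in seed_sets:
        pair = build_halfsite_pwms(
            align_res(seeds), pseudocount=pseudocount, background=background
        )
        rankings.append(
            rank_candidates(
                candidates, pair, background,
                evalue_cutoff=evalue_cutoff, alpha=alpha,
            )
        )
    ref = rankings[0]
    rows = []
    for i, rk in enumerate(rankings):
        rows.append(
            {
                "seed_set": i + 1,
                "n_mast": len(rk.significant_mast),
                "n_scan": len(rk.significant_scan),
                "n_consensus": len(rk.consensus),
                "mast_overlap_with_ref": len(
                    set(rk.significant_mast) & set(ref.significant_mast)
                ),
                "scan_overlap_with_ref": len(
                    set(rk.significant_scan) & set(ref.significant_scan)
                ),
                "consensus_overlap_with_ref": len(
                    set(rk.consensus) & set(ref.consensus)
                ),
            }
        )
    return pd.DataFrame(rows)
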