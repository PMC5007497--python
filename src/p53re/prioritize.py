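"""Deterministic candidate filtering and ranking-merge around external tools.

Gene-prioritization services (Endeavour, ToppGene, Biomart orthology) are
consumed as user-supplied TSV exports, never called; this module reproduces
the bookkeeping: region/TSS/strand filters on annotated patterns, the
one-to-one ortholog join, and the union of per-tool top-k rankings with
provenance.  The final manual-curation step of candidate selection is
deliberately not automated — the output is the filtered pool with
provenance columns for human review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import PatternAnnotation

__all__ = [
    "PrioritizationCriteria",
    "OrthologPair",
    "filter_candidates",
    "join_orthologs",
    "load_ortholog_table",
    "merge_rankings",
]

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")


@dataclass
class PrioritizationCriteria:
    """Boolean filters applied to annotated patterns; ``None`` disables a
    criterion.  Defaults keep promoter-proximal candidates: upstream or
    5'UTR hits, any TSS distance, no strand requirement."""

    allowed_regions: set[str] | None = field(
        default_factory=lambda: {"upstream", "five_prime_UTR"}
    )
    max_abs_tss_distance: int | None = None
    require_strand_concordance: bool = False
    min_patterns_per_gene: int = 1
    top_k_per_ranking: int = 50

    def __post_init__(self) -> None:
        if self.top_k_per_ranking < 1:
            raise ValueError("top_k_per_ranking must be >= 1")


@dataclass(frozen=True)
class OrthologPair:
    source_id: str
    target_id: str
    homology_type: str

    def __post_init__(self) -> None:
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValueError(
                f"homology_type must be one of {HOMOLOGY_TYPES}, "
                f"got {self.homology_type!r}"
            )


def filter_candidates(
    annotations: list[PatternAnnotation], criteria: PrioritizationCriteria
) -> list[PatternAnnotation]:
    """Keep annotations passing every enabled criterion; order-preserving
    and idempotent.  Empty criteria (all None/False/1) is the identity."""
    out = []
    for a in annotations:
        if criteria.allowed_regions is not None and a.region_label not in criteria.allowed_regions:
            continue
        if (
            criteria.max_abs_tss_distance is not None
            and abs(a.distance_to_tss) > criteria.max_abs_tss_distance
        ):
            continue
        if criteria.require_strand_concordance and not a.strand_concordant:
            continue
        if a.n_patterns_for_gene < criteria.min_patterns_per_gene:
            continue
        out.append(a)
    return out


def load_ortholog_table(path) -> list[OrthologPair]:
    """Read a TSV with columns source_id, target_id, homology_type."""
    df = pd.read_csv(path, sep="\t")
    required = {"source_id", "target_id", "homology_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"ortholog table must have columns {sorted(required)}")
    return [
        OrthologPair(r.source_id, r.target_id, r.homology_type)
        for r in df.itertuples()
    ]


def join_orthologs(
    genes: list[str], pairs: list[OrthologPair], keep: str = "one2one"
) -> dict[str, str | None]:
    """Map each gene to its ortholog of the kept homology type, or ``None``.

    Conflicting one-to-one rows for the same source gene are an error (they
    contradict the claimed relationship).
    """
    mapping: dict[str, str] = {}
    for p in pairs:
        if p.homology_type != keep:
            continue
        if p.source_id in mapping and mapping[p.source_id] != p.target_id:
            raise ValueError(
                f"conflicting {keep} rows for {p.source_id}: "
                f"{mapping[p.source_id]} vs {p.target_id}"
            )
        mapping[p.source_id] = p.target_id
    return {g: mapping.get(g) for g in genes}


def merge_rankings(
    ranking_files: list, top_k: int = 50, names: list[str] | None = None
) -> pd.DataFrame:
    """Union of each ranking file's top-k genes with per-tool provenance.

    Each TSV needs gene_id plus a rank (or score to rank by, descending).
    Returns one row per admitted gene with boolean ``in_<tool>`` columns
    and the best (smallest) rank that admitted it.
    """
    if names is None:
        names = [f"ranking{i + 1}" for i in range(len(ranking_files))]
    admitted: dict[str, dict] = {}
    for name, path in zip(names, ranking_files):
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns:
            raise ValueError(f"{path}: missing gene_id column")
        if "rank" in df.columns:
            df = df.sort_values("rank", kind="stable")
        elif "score" in df.columns:
            df = df.sort_values("score", ascending=False, kind="stable")
        else:
            raise ValueError(f"{path}: need a rank or score column")
        for pos, gene in enumerate(df["gene_id"].head(top_k), start=1):
            rec = admitted.setdefault(
                gene, {"gene_id": gene, "best_rank": pos}
            )
            rec[f"in_{name}"] = True
            rec["best_rank"] = min(rec["best_rank"], pos)
    out = pd.DataFrame(list(admitted.values()))
    if out.empty:
        return pd.DataFrame(columns=["gene_id", "best_rank"])
    for name in names:
        col = f"in_{name}"
        if col not in out.columns:
            out[col] = False
        out[col] = out[col].eq(True)
    return out.sort_values(["best_rank", "gene_id"], kind="stable").reset_index(
        drop=True
    )
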