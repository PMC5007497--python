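"""Sequence containers, FASTA I/O and the IUPAC degenerate-nucleotide alphabet.

Everything downstream (scanning, PWM scoring, simulation) consumes the
:class:`Genome` container defined here.  Coordinates are 0-based half-open
internally; user-facing tables are converted to 1-based inclusive at the
I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_TABLE",
    "IUPAC_COMPLEMENT",
    "SequenceRecord",
    "Genome",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_matches",
    "encode_sequence",
]

# IUPAC degenerate nucleotide codes: symbol -> set of concrete bases matched.
# Note: a genome 'N' (assembly gap) matches NO symbol, not even pattern 'N';
# the pattern-side 'N' is only used to denote the unconstrained spacer run,
# whose positions are never tested against the alphabet at all.
IUPAC_TABLE: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),   # purine
    "Y": frozenset("CT"),   # pyrimidine
    "W": frozenset("AT"),   # weak
    "S": frozenset("CG"),   # strong
    "K": frozenset("GT"),   # keto
    "M": frozenset("AC"),   # amino
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "W": "W", "S": "S",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMP_TRANSLATION = str.maketrans(
    "".join(IUPAC_COMPLEMENT) + "".join(IUPAC_COMPLEMENT).lower(),
    "".join(IUPAC_COMPLEMENT.values()) + "".join(IUPAC_COMPLEMENT.values()).lower(),
)

# Base encoding used by the vectorised scanner: A=0 C=1 G=2 T=3, anything
# else (N, gaps, unexpected letters) = 4.  Case-insensitive by construction.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


@dataclass
class SequenceRecord:
    """One chromosome/contig: a name and its (case-preserved) sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Genome:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in genome")
        self._index = {r.id: r for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __getitem__(self, chrom: str) -> SequenceRecord:
        return self._index[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice a record with 0-based half-open coordinates."""
        return self._index[chrom].seq[start:end]

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide A/C/G/T frequencies (case-insensitive, N excluded)."""
        counts = np.zeros(5, dtype=np.int64)
        for rec in self.records:
            codes = encode_sequence(rec.seq)
            counts += np.bincount(codes, minlength=5)
        total = counts[:4].sum()
        if total == 0:
            return {b: 0.25 for b in "ACGT"}
        return {b: counts[i] / total for i, b in enumerate("ACGT")}


def read_fasta(path) -> Genome:
    """Read a (multi-record, wrapped or unwrapped) FASTA file into a Genome.

    Case is preserved so soft-masked regions stay identifiable; matching is
    case-insensitive downstream.  An empty file yields an empty Genome.
    """
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Genome(records=records)


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    """Write a Genome to FASTA with the given line width."""
    bio = [
        _BioSeqRecord(Seq(rec.seq), id=rec.id, description="")
        for rec in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide/IUPAC string (case preserved).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Raises ``ValueError`` on characters outside the IUPAC alphabet.
    """
    for ch in seq:
        if ch.upper() not in IUPAC_TABLE:
            raise ValueError(f"non-IUPAC character {ch!r} in sequence")
    return seq.translate(_COMP_TRANSLATION)[::-1]


def iupac_matches(symbol: str, base: str) -> bool:
    """True iff concrete ``base`` satisfies degenerate ``symbol``.

    A genome base N (or any non-ACGT character) satisfies nothing — assembly
    gaps never produce half-site matches.
    """
    sym = symbol.upper()
    if sym not in IUPAC_TABLE:
        raise ValueError(f"unknown IUPAC symbol {symbol!r}")
    return base.upper() in IUPAC_TABLE[sym]


def symbol_lut(symbol: str) -> np.ndarray:
    """Boolean lookup over the 5-code base encoding for one IUPAC symbol."""
    sym = symbol.upper()
    if sym not in IUPAC_TABLE:
        raise ValueError(f"unknown IUPAC symbol {symbol!r}")
    lut = np.zeros(5, dtype=bool)
    for base in IUPAC_TABLE[sym]:
        lut["ACGT".index(base)] = True
    return lut
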