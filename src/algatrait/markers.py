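"""Pairwise divergence of aligned marker-gene sequences.

Compares two pre-aligned nucleotide sequences (SSU/LSU rDNA, ITS, rbcL)
column by column: substitutions are columns with two unlike unambiguous
bases, gap columns have a gap in exactly one sequence, and the percent
dissimilarity counts both over the full alignment length. Alignment itself
is out of scope — inputs are already-aligned pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

ALLOWED_CHARS = frozenset("ACGTN-")
MARKERS = ("SSU", "ITS", "LSU", "rbcL")


class MarkerError(ValueError):
    """Invalid marker-pair input."""


@dataclass(frozen=True)
class MarkerAlignmentPair:
    """Two aligned, equal-length nucleotide sequences for one marker locus."""

    query_id: str
    reference_id: str
    query_seq: str
    reference_seq: str
    marker: str = "SSU"

    def __post_init__(self) -> None:
        q = self.query_seq.upper()
        r = self.reference_seq.upper()
        object.__setattr__(self, "query_seq", q)
        object.__setattr__(self, "reference_seq", r)
        if len(q) == 0:
            raise MarkerError("empty alignment")
        if len(q) != len(r):
            raise MarkerError(
                f"aligned lengths differ: {len(q)} vs {len(r)}"
            )
        bad = (set(q) | set(r)) - ALLOWED_CHARS
        if bad:
            raise MarkerError(f"disallowed characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.query_seq)


@dataclass(frozen=True)
class DivergenceResult:
    """Column-wise divergence counts and the gap-inclusive dissimilarity."""

    substitutions: int
    gap_columns: int
    compared_length: int
    dissimilarity_percent: float  # full precision; round for display

    @property
    def dissimilarity_rounded(self) -> float:
        """Percent rounded half-up to one decimal, display convention."""
        return _round_half_up(self.dissimilarity_percent, 1)


def _round_half_up(x: float, ndigits: int) -> float:
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def compare_pair(pair: MarkerAlignmentPair) -> DivergenceResult:
    """Count substitutions and one-sided gap columns across the alignment.

    Columns containing N in either sequence are never mismatches but still
    count toward the compared length; dissimilarity = 100·(subs + gaps)/length.
    """
    subs = 0
    gaps = 0
    for a, b in zip(pair.query_seq, pair.reference_seq):
        a_gap, b_gap = a == "-", b == "-"
        if a_gap != b_gap:
            gaps += 1
        elif not a_gap and a != b and a != "N" and b != "N":
            subs += 1
    length = len(pair)
    return DivergenceResult(
        substitutions=subs,
        gap_columns=gaps,
        compared_length=length,
        dissimilarity_percent=100.0 * (subs + gaps) / length,
    )


def read_fasta_pair(path: str | Path, marker: str = "SSU") -> MarkerAlignmentPair:
    """Read a two-record aligned FASTA; first record is the query.

    Lowercase bases are uppercased on ingest.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise MarkerError(
            f"{path}: expected exactly 2 records, found {len(records)}"
        )
    q, r = records
    if len(q.seq) != len(r.seq):
        raise MarkerError(
            f"{path}: records have unequal aligned lengths "
            f"({len(q.seq)} vs {len(r.seq)})"
        )
    return MarkerAlignmentPair(
        query_id=q.id,
        reference_id=r.id,
        query_seq=str(q.seq),
        reference_seq=str(r.seq),
        marker=marker,
    )
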