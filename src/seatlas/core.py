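"""Shared genomic data types and interval arithmetic.

Coordinates are 0-based, half-open (BED convention) throughout the
package; GFF3 input (1-based, closed) is converted at the I/O boundary.
All region-level operations in the toolkit — ACR union building,
nonpromoter-ACR clustering, promoter-window overlap, closest-gene
search — reduce to the three primitives defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeIndex",
    "merge_intervals",
    "interval_distance",
    "overlap_length",
    "point_interval_distance",
]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with mandatory strand and an ordered exon chain.

    The TSS is the strand-aware 5' boundary coordinate and the TTS the
    3' one: for a ``+`` gene ``tss == interval.start``; for a ``-``
    gene ``tss == interval.end``.  Introns are the gaps between
    consecutive exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")
        prev_end = None
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(f"exon {ex} outside gene {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.gene_id} not sorted/disjoint")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def introns(self) -> list:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return out

    def promoter_window(self, upstream_bp: int = 500) -> GenomicInterval:
        """Strand-aware window immediately upstream of the TSS.

        ``[tss - upstream_bp, tss)`` for ``+`` genes and
        ``[tss, tss + upstream_bp)`` for ``-`` genes; the TSS base
        itself is excluded by convention.  Clipped at position 0.
        """
        if self.strand == "+":
            return GenomicInterval(
                self.interval.chrom, max(0, self.tss - upstream_bp), max(1, self.tss)
            )
        return GenomicInterval(self.interval.chrom, self.tss, self.tss + upstream_bp)


class GenomeIndex:
    """Chromosome lengths plus an optional sequence accessor.

    ``sequences`` may be any mapping of chromosome name to an object
    supporting slicing that yields a string-convertible sequence (a
    plain ``str``, a ``pyfaidx.FastaRecord``, ...).
    """

    def __init__(
        self,
        lengths: Mapping[str, int],
        sequences: Optional[Mapping[str, object]] = None,
    ):
        self.lengths = dict(lengths)
        self._sequences = sequences

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeIndex":
        return cls({c: len(s) for c, s in sequences.items()}, sequences)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: len(fa[name]) for name in fa.keys()}, fa)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def check(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(
                f"{iv} beyond chromosome end ({self.lengths[iv.chrom]})"
            )

    def fetch(self, iv: GenomicInterval) -> str:
        """Uppercase sequence of *iv*; requires a sequence accessor."""
        if self._sequences is None:
            raise ValueError("GenomeIndex has no sequence accessor")
        self.check(iv)
        return str(self._sequences[iv.chrom][iv.start : iv.end]).upper()


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list:
    """Merge intervals chained by gaps of at most ``max_gap`` bp.

    The gap between two intervals on the same chromosome is
    ``start_next - end_prev``; overlapping or touching intervals have
    gap <= 0 and always merge.  ``max_gap=49`` realizes the
    "less than 50 bp apart" clustering rule.  Output is sorted and
    pairwise disjoint per chromosome, and its union covers the union
    of the input.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals; 0 if they overlap or touch.

    Returns ``None`` (the cross-chromosome sentinel) when the intervals
    lie on different chromosomes — never a large number, so that
    closest-feature searches cannot silently mix chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bp; 0 when disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance in bp from a point coordinate to an interval (0 if inside)."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end
    return 0


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by a pre-merged (disjoint) interval list."""
    return sum(iv.length for iv in intervals)
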