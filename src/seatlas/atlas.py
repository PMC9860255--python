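"""Multi-sample ACR atlas: union building, promoter classification,
and DNase I sensitivity.

An ACR (accessible chromatin region) is the atom of the analysis: a
merged open-chromatin interval carrying the set of samples that
support it and a promoter/nonpromoter class.  An ACR is a promoter
ACR when it overlaps the strand-aware 500-bp window upstream of any
gene's TSS by at least ``min_overlap`` bp (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, merge_intervals, overlap_length
from .peaks import Peak, ReadStartTrack

PROMOTER = "promoter"
NONPROMOTER = "nonpromoter"


@dataclass
class Sample:
    sample_id: str
    tissue: str = ""
    peaks: List[Peak] = field(default_factory=list)
    tracks: Optional[Dict[str, ReadStartTrack]] = None  # chrom → track


@dataclass
class ACR:
    acr_id: str
    interval: GenomicInterval
    supporting_samples: frozenset
    acr_class: Optional[str] = None
    sensitivity: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.supporting_samples:
            raise ValueError(f"{self.acr_id}: no supporting samples")


def build_union_acrs(samples: Sequence[Sample]) -> List[ACR]:
    """Merge all samples' peaks (overlap-merge) into the ACR union.

    Each union ACR records every sample contributing >= 1 bp of peak
    overlap.  Raises if no sample carries any peak.
    """
    all_ivs = [p.interval for s in samples for p in s.peaks]
    if not all_ivs:
        raise ValueError("no peaks in any sample")
    merged = merge_intervals(all_ivs, max_gap=0)

    trees: Dict[str, IntervalTree] = {}
    for i, iv in enumerate(merged):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    support: List[set] = [set() for _ in merged]
    for s in samples:
        for p in s.peaks:
            tree = trees.get(p.interval.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(p.interval.start, p.interval.end):
                support[hit.data].add(s.sample_id)

    width = max(4, len(str(len(merged))))
    return [
        ACR(f"ACR{i + 1:0{width}d}", iv, frozenset(support[i]))
        for i, iv in enumerate(merged)
    ]


def classify_acrs(
    acrs: Sequence[ACR],
    genes: Sequence[GeneModel],
    upstream_bp: int = 500,
    min_overlap: int = 1,
) -> List[ACR]:
    """Label each ACR promoter or nonpromoter (in place; returns list).

    The promoter window is ``[tss - upstream_bp, tss)`` for ``+``
    genes and ``[tss, tss + upstream_bp)`` for ``-`` genes.
    """
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id} is unstranded")
        w = g.promoter_window(upstream_bp)
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)

    for acr in acrs:
        tree = trees.get(acr.interval.chrom)
        is_prom = False
        if tree is not None:
            for hit in tree.overlap(acr.interval.start, acr.interval.end):
                ov = min(hit.end, acr.interval.end) - max(hit.begin, acr.interval.start)
                if ov >= min_overlap:
                    is_prom = True
                    break
        acr.acr_class = PROMOTER if is_prom else NONPROMOTER
    return list(acrs)


def dnase_sensitivity(acr: ACR, sample: Sample) -> float:
    """Reads per bp per million mapped reads within the ACR.

    Combines both normalizations in one number: read count in the ACR
    divided by ACR length (bp) and by library size in millions.
    """
    if sample.tracks is None:
        raise ValueError(f"sample {sample.sample_id} has no read tracks")
    track = sample.tracks.get(acr.interval.chrom)
    if track is None:
        n_in = 0
        total = next(iter(sample.tracks.values())).total_mapped_reads
    else:
        total = track.total_mapped_reads
        lo = np.searchsorted(track.positions, acr.interval.start, side="left")
        hi = np.searchsorted(track.positions, acr.interval.end, side="left")
        n_in = int(hi - lo)
    if total == 0:
        raise ValueError(f"sample {sample.sample_id}: total_mapped_reads is 0")
    return n_in / acr.interval.length / (total / 1e6)


def annotate_sensitivity(acrs: Sequence[ACR], samples: Sequence[Sample]) -> None:
    for acr in acrs:
        for s in samples:
            if s.tracks is not None:
                acr.sensitivity[s.sample_id] = dnase_sensitivity(acr, s)


def promoter_fraction(acrs: Sequence[ACR]) -> float:
    n = sum(1 for a in acrs if a.acr_class == PROMOTER)
    return n / len(acrs)
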