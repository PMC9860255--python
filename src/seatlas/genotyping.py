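"""Presence/absence genotyping of a known insertion from read pairs.

Three junction references are assembled for each insertion locus: the
left joint (upstream flank + element 5' end), the right joint
(element 3' end + downstream flank) and the cross joint (the two
genomic flanks concatenated, element absent).  A read pair supports a
junction when both mates map to its reference — exact substring or up
to ``max_mismatches`` mismatches, each mate fully contained — on
opposite sides of the joint midpoint.  The call rule is exact:

* present  iff n_left >= min_pairs and n_right >= min_pairs and n_cross == 0
* absent   iff n_cross >= min_pairs and n_left == 0 and n_right == 0
* otherwise ambiguous (including heterozygous-like mixed evidence)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomeIndex, GenomicInterval

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionLocus:
    """Coordinates of the inserted element in the insertion-bearing
    haplotype, plus the flank size used to build junctions."""

    locus_id: str
    chrom: str
    insertion_start: int
    insertion_end: int
    flank: int = 200

    def __post_init__(self) -> None:
        if self.insertion_end <= self.insertion_start:
            raise ValueError(f"{self.locus_id}: empty insertion span")
        if self.flank <= 0:
            raise ValueError(f"{self.locus_id}: flank must be > 0")


@dataclass(frozen=True)
class JunctionSet:
    left_joint: str
    right_joint: str
    cross_joint: str
    flank: int

    def __post_init__(self) -> None:
        for name in ("left_joint", "right_joint", "cross_joint"):
            if len(getattr(self, name)) != 2 * self.flank:
                raise ValueError(f"{name} is not 2 x flank long")


@dataclass(frozen=True)
class InsertionEvidence:
    n_left: int
    n_right: int
    n_cross: int

    def __post_init__(self) -> None:
        if min(self.n_left, self.n_right, self.n_cross) < 0:
            raise ValueError("negative evidence count")


@dataclass(frozen=True)
class GenotypeCall:
    call: str
    evidence: InsertionEvidence


def build_junctions(
    genome: GenomeIndex, element_seq: str, locus: InsertionLocus
) -> JunctionSet:
    """Assemble the three junction references for a locus.

    The genomic flanks are taken around ``[insertion_start,
    insertion_end)``; the element sequence provides the 5' and 3'
    ends of the joints and must be at least ``flank`` bp long.
    """
    f = locus.flank
    element_seq = element_seq.upper()
    if len(element_seq) < f:
        raise ValueError(
            f"{locus.locus_id}: element ({len(element_seq)} bp) shorter than flank"
        )
    if locus.insertion_start - f < 0:
        raise ValueError(f"{locus.locus_id}: upstream flank runs past chromosome start")
    upstream = genome.fetch(
        GenomicInterval(locus.chrom, locus.insertion_start - f, locus.insertion_start)
    )
    downstream = genome.fetch(
        GenomicInterval(locus.chrom, locus.insertion_end, locus.insertion_end + f)
    )
    return JunctionSet(
        left_joint=upstream + element_seq[:f],
        right_joint=element_seq[-f:] + downstream,
        cross_joint=upstream + downstream,
        flank=f,
    )


def _find_match(mate: str, ref: str, max_mismatches: int) -> Optional[Tuple[int, int]]:
    """Best full-length placement of *mate* (either orientation) in
    *ref* with at most ``max_mismatches`` mismatches."""
    m = len(mate)
    if m > len(ref):
        return None
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = None
    for seq in (mate, _revcomp(mate)):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, m)
        mismatches = (windows != arr).sum(axis=1)
        i = int(np.argmin(mismatches))
        if mismatches[i] <= max_mismatches and (best is None or mismatches[i] < best[0]):
            best = (int(mismatches[i]), i, i + m)
    return None if best is None else (best[1], best[2])


def pair_spans_junction(
    mate1: str, mate2: str, junction: str, flank: int, max_mismatches: int = 2
) -> bool:
    """True when the mates map to the junction on opposite sides of
    the joint midpoint (a mate crossing the midpoint counts for
    neither side)."""
    loc1 = _find_match(mate1.upper(), junction, max_mismatches)
    loc2 = _find_match(mate2.upper(), junction, max_mismatches)
    if loc1 is None or loc2 is None:
        return False
    mid = flank
    left_of = lambda loc: loc[1] <= mid
    right_of = lambda loc: loc[0] >= mid
    return (left_of(loc1) and right_of(loc2)) or (left_of(loc2) and right_of(loc1))


def count_spanning_pairs(
    read_pairs: Sequence[Tuple[str, str]],
    junctions: JunctionSet,
    max_mismatches: int = 2,
) -> InsertionEvidence:
    """Accumulate junction-spanning read-pair counts for one locus."""
    counts = {"left": 0, "right": 0, "cross": 0}
    refs = {
        "left": junctions.left_joint,
        "right": junctions.right_joint,
        "cross": junctions.cross_joint,
    }
    for mate1, mate2 in read_pairs:
        for name, ref in refs.items():
            if pair_spans_junction(mate1, mate2, ref, junctions.flank, max_mismatches):
                counts[name] += 1
    return InsertionEvidence(counts["left"], counts["right"], counts["cross"])


def classify_insertion(evidence: InsertionEvidence, min_pairs: int = 4) -> GenotypeCall:
    """Apply the rule table to junction-spanning evidence."""
    e = evidence
    if e.n_left >= min_pairs and e.n_right >= min_pairs and e.n_cross == 0:
        return GenotypeCall(PRESENT, e)
    if e.n_cross >= min_pairs and e.n_left == 0 and e.n_right == 0:
        return GenotypeCall(ABSENT, e)
    return GenotypeCall(AMBIGUOUS, e)
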