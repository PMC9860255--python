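"""Super-enhancer calling from clustered nonpromoter ACRs.

The definition is size-based: nonpromoter ACRs less than 50 bp apart
are chained into clusters, and the clusters whose spans fall in the
top 2.5% of lengths are the super-enhancers (SEs).  Each SE is
assigned the closest gene as its putative cognate gene and a genomic
position class (genic — further split into single-intron, exonic or
multi-feature — or intergenic, with 5'/3' flank sub-classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .atlas import ACR, NONPROMOTER
from .core import (
    GeneModel,
    GenomicInterval,
    interval_distance,
    overlap_length,
    point_interval_distance,
)

GENIC_MULTIFEATURE = "genic_multifeature"
GENIC_SINGLE_INTRON = "genic_single_intron"
GENIC_EXONIC = "genic_exonic"
INTERGENIC = "intergenic"

FIVE_PRIME_OF_A_FLANK = "five_prime_of_a_flank"
THREE_PRIME_OF_BOTH = "three_prime_of_both"

#: Cluster length (bp) above which the top 2.5% fell at publication scale.
FULL_SCALE_SE_LENGTH_THRESHOLD = 1500


@dataclass
class ACRCluster:
    """A chain of nonpromoter ACRs with consecutive gaps <= 49 bp."""

    interval: GenomicInterval
    constituents: List[ACR]

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class SuperEnhancer:
    se_id: str
    interval: GenomicInterval
    constituents: List[ACR]
    cognate_gene: Optional[str] = None
    cognate_distance: Optional[int] = None
    position_class: Optional[str] = None
    intergenic_subclass: Optional[str] = None
    nearest_end_distance: Optional[int] = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


def cluster_nonpromoter_acrs(
    acrs: Sequence[ACR], max_gap: int = 49
) -> List[ACRCluster]:
    """Chain nonpromoter ACRs whose gaps are at most ``max_gap`` bp.

    Singleton ACRs form singleton clusters.  Promoter ACRs are
    ignored; unclassified ACRs raise.
    """
    nonprom = []
    for a in acrs:
        if a.acr_class is None:
            raise ValueError(f"{a.acr_id} is unclassified; run classify_acrs first")
        if a.acr_class == NONPROMOTER:
            nonprom.append(a)
    nonprom.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    clusters: List[ACRCluster] = []
    current: List[ACR] = []
    cur_end = -1  # running max end of the open cluster
    for a in nonprom:
        if (
            current
            and a.interval.chrom == current[-1].interval.chrom
            and a.interval.start - cur_end <= max_gap
        ):
            current.append(a)
            cur_end = max(cur_end, a.interval.end)
        else:
            if current:
                clusters.append(_make_cluster(current))
            current = [a]
            cur_end = a.interval.end
    if current:
        clusters.append(_make_cluster(current))
    return clusters


def _make_cluster(members: List[ACR]) -> ACRCluster:
    iv = GenomicInterval(
        members[0].interval.chrom,
        members[0].interval.start,
        max(m.interval.end for m in members),
    )
    return ACRCluster(iv, list(members))


def select_super_enhancers(
    clusters: Sequence[ACRCluster],
    top_fraction: float = 0.025,
    length_threshold: Optional[int] = None,
) -> Tuple[List[SuperEnhancer], int]:
    """Select SEs as the top length quantile of clusters.

    By default the quantile is primary: clusters are sorted by length
    descending (ties by genomic coordinate, then chromosome name),
    ``k = ceil(top_fraction * n)`` clusters are taken, and the
    returned threshold is the k-th length.  Passing
    ``length_threshold`` switches to a fixed bp cutoff instead
    (clusters with length >= threshold), e.g. the 1.5-kb value the
    quantile resolves to at publication scale.
    """
    if not clusters:
        raise ValueError("no clusters")
    if length_threshold is None and not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    ranked = sorted(
        clusters,
        key=lambda c: (-c.length, c.interval.start, c.interval.chrom),
    )
    if length_threshold is not None:
        chosen = [c for c in ranked if c.length >= length_threshold]
        threshold = int(length_threshold)
    else:
        k = math.ceil(top_fraction * len(ranked))
        chosen = ranked[:k]
        threshold = chosen[-1].length
    chosen.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    width = max(3, len(str(len(chosen))))
    ses = [
        SuperEnhancer(f"SE{i + 1:0{width}d}", c.interval, list(c.constituents))
        for i, c in enumerate(chosen)
    ]
    return ses, threshold


def assign_cognate_gene(
    se: SuperEnhancer, genes: Sequence[GeneModel]
) -> Tuple[Optional[str], Optional[int]]:
    """Closest gene to the SE span (gene-body anchored).

    Ties on body distance are broken by smaller |SE midpoint - TSS|,
    then lexicographic gene id.  On a gene-free chromosome returns
    ``(None, None)`` and the SE is left flagged.
    """
    best = None
    mid = se.interval.midpoint
    for g in genes:
        d = interval_distance(se.interval, g.interval)
        if d is None:
            continue
        key = (d, abs(mid - g.tss), g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None:
        return None, None
    se.cognate_gene = best[1].gene_id
    se.cognate_distance = best[0][0]
    return se.cognate_gene, se.cognate_distance


def classify_se_position(
    se: SuperEnhancer,
    genes: Sequence[GeneModel],
    genic_overlap_frac: float = 0.5,
) -> str:
    """Assign the SE's genomic position class.

    Genic iff at least ``genic_overlap_frac`` of the SE length
    overlaps a single gene body; genic SEs fully inside one intron or
    one exon get the corresponding subclass, else multi-feature.
    Intergenic SEs are sub-classed by the orientation of their two
    flanking genes: 5' of at least one flank, or 3' of both
    (convergent flanks).  ``nearest_end_distance`` is the minimum
    distance to any TSS or TTS.
    """
    same_chrom = [g for g in genes if g.interval.chrom == se.interval.chrom]
    host = None
    host_ov = 0
    for g in same_chrom:
        ov = overlap_length(se.interval, g.interval)
        if ov > host_ov:
            host, host_ov = g, ov
    ends = [
        point_interval_distance(p, se.interval)
        for g in same_chrom
        for p in (g.tss, g.tts)
    ]
    se.nearest_end_distance = min(ends) if ends else None

    if host is not None and host_ov >= genic_overlap_frac * se.length:
        se.position_class = GENIC_MULTIFEATURE
        for intron in host.introns:
            if intron.contains(se.interval):
                se.position_class = GENIC_SINGLE_INTRON
                break
        else:
            for exon in host.exons:
                if exon.contains(se.interval):
                    se.position_class = GENIC_EXONIC
                    break
        se.intergenic_subclass = None
        return se.position_class

    se.position_class = INTERGENIC
    left = None
    right = None
    for g in same_chrom:
        if g.interval.end <= se.interval.start:
            if left is None or g.interval.end > left.interval.end:
                left = g
        elif g.interval.start >= se.interval.end:
            if right is None or g.interval.start < right.interval.start:
                right = g
    # SE is strand-upstream of a gene when it sits on the gene's 5' side
    upstream_of_left = left is not None and left.strand == "-"
    upstream_of_right = right is not None and right.strand == "+"
    if upstream_of_left or upstream_of_right:
        se.intergenic_subclass = FIVE_PRIME_OF_A_FLANK
    elif (
        left is not None
        and right is not None
        and left.strand == "+"
        and right.strand == "-"
    ):
        se.intergenic_subclass = THREE_PRIME_OF_BOTH
    else:
        se.intergenic_subclass = None
    return se.position_class


@dataclass
class AtlasSummary:
    """Headline counts of an SE atlas, with report-ready percentages.

    Percentages are rounded to the nearest integer for parity with
    published summaries; unrounded values are kept alongside.
    """

    n_acrs: int
    promoter_fraction: float
    n_clusters: int
    n_ses: int
    se_length_threshold: int
    mean_se_length: float
    se_length_range: Tuple[int, int]
    mean_constituents: float
    n_genic: int
    n_intergenic: int
    fraction_within_d_of_gene_end: Dict[int, float] = field(default_factory=dict)

    @property
    def genic_percent(self) -> int:
        return round(100 * self.n_genic / self.n_ses)

    @property
    def promoter_percent(self) -> int:
        return round(100 * self.promoter_fraction)

    def to_dict(self) -> dict:
        return {
            "n_acrs": self.n_acrs,
            "promoter_fraction": self.promoter_fraction,
            "promoter_percent": self.promoter_percent,
            "n_clusters": self.n_clusters,
            "n_ses": self.n_ses,
            "se_length_threshold": self.se_length_threshold,
            "mean_se_length": self.mean_se_length,
            "se_length_min": self.se_length_range[0],
            "se_length_max": self.se_length_range[1],
            "mean_constituents": self.mean_constituents,
            "n_genic": self.n_genic,
            "n_intergenic": self.n_intergenic,
            "genic_percent": self.genic_percent,
            "fraction_within_d_of_gene_end": {
                str(k): v for k, v in self.fraction_within_d_of_gene_end.items()
            },
        }


def summarize_atlas(
    acrs: Sequence[ACR],
    clusters: Sequence[ACRCluster],
    ses: Sequence[SuperEnhancer],
    se_length_threshold: int,
    near_distances: Sequence[int] = (3200,),
) -> AtlasSummary:
    """Compute the atlas summary; requires position classes assigned."""
    n_genic = sum(1 for s in ses if s.position_class and s.position_class.startswith("genic"))
    intergenic = [s for s in ses if s.position_class == INTERGENIC]
    frac_near = {}
    for d in near_distances:
        pool = [s for s in intergenic if s.nearest_end_distance is not None]
        frac_near[d] = (
            sum(1 for s in pool if s.nearest_end_distance <= d) / len(pool)
            if pool
            else float("nan")
        )
    lengths = [s.length for s in ses]
    return AtlasSummary(
        n_acrs=len(acrs),
        promoter_fraction=sum(1 for a in acrs if a.acr_class == "promoter") / len(acrs),
        n_clusters=len(clusters),
        n_ses=len(ses),
        se_length_threshold=se_length_threshold,
        mean_se_length=sum(lengths) / len(lengths) if lengths else float("nan"),
        se_length_range=(min(lengths), max(lengths)) if lengths else (0, 0),
        mean_constituents=(
            sum(s.n_constituents for s in ses) / len(ses) if ses else float("nan")
        ),
        n_genic=n_genic,
        n_intergenic=len(ses) - n_genic,
        fraction_within_d_of_gene_end=frac_near,
    )
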