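"""Synteny-anchored cross-species conservation of SE sequences.

The search strategy mirrors comparative work on plant regulatory
elements: for each intergenic SE, take the two flanking genes; if the
pair has syntenic partners that are still adjacent (no intervening
gene) in a target species, align the SE sequence to the intergenic
sequence between the partners with a local aligner and summarize the
aligned fraction, sequence identity (matched nucleotides over aligned
columns), and TF-motif retention.  A resampling test compares synteny
maintenance of SE-spanning gene pairs against pairs without SEs.

The local aligner is iterated masked Smith-Waterman (Gotoh affine
gaps, both strands) built on Biopython's pairwise aligner: after each
accepted hit the query span is masked and the next-best hit extracted,
so several sub-regions of an SE can match disjoint parts of the
target, as a seed-and-extend tool would report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import GeneModel, GenomicInterval, overlap_length
from .se import INTERGENIC, SuperEnhancer

SYNTENIC_ADJACENT = "syntenic_adjacent"
SYNTENIC_NONADJACENT = "syntenic_nonadjacent"
ABSENT = "absent"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LocalAlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    # Gap costs are deliberately stiff: mild affine costs let the
    # optimizer buy spurious matches with paired micro-gaps in highly
    # diverged sequence, inflating the identity estimate by ~3 points
    # at 40% divergence.  These defaults keep planted divergence
    # recoverable to within about half a point.
    gap_open: float = -5.0  # first gap column
    gap_extend: float = -2.0  # each further column
    min_identity: float = 0.70  # fraction, per accepted hit
    min_hit_len: int = 30  # bp of query per accepted hit
    max_hits: int = 50


@dataclass(frozen=True)
class LocalHit:
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    columns: int
    score: float

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns


def _make_aligner(p: LocalAlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    mat = substitution_matrices.Array("ACGTNX", dims=2)
    for x in "ACGTNX":
        for y in "ACGTNX":
            if x in "ACGT" and y in "ACGT":
                mat[x, y] = p.match if x == y else p.mismatch
            else:
                # N never matches; X marks masked query positions
                mat[x, y] = -1000.0
    aligner.substitution_matrix = mat
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _alignment_stats(aln, query: str, target: str) -> Tuple[int, int, int, int, int, int]:
    """(matches, columns, q_start, q_end, t_start, t_end) of a local alignment."""
    qblocks, tblocks = aln.aligned
    matches = 0
    columns = 0
    prev_qe = prev_te = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_qe is not None:
            columns += (qs - prev_qe) + (ts - prev_te)
        for i, j in zip(range(qs, qe), range(ts, te)):
            columns += 1
            qc, tc = query[i], target[j]
            if qc == tc and qc in "ACGT":
                matches += 1
        prev_qe, prev_te = qe, te
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
    return matches, columns, q_start, q_end, t_start, t_end


def local_align(
    query: str, target: str, params: Optional[LocalAlignParams] = None
) -> List[LocalHit]:
    """Iterated masked local alignment of *query* against *target*.

    The best-scoring Smith-Waterman hit (either strand of the target)
    is extracted, its query span masked, and the search repeated until
    the best score falls below the minimum an acceptable hit could
    score.  Hits failing ``min_identity`` or ``min_hit_len`` are
    masked but not reported.  Reverse-strand hits carry target
    coordinates on the forward strand.
    """
    p = params or LocalAlignParams()
    if not query or not target:
        raise ValueError("empty sequence")
    query = query.upper()
    targets = {"+": target.upper(), "-": revcomp(target.upper())}
    aligner = _make_aligner(p)
    # lowest score an acceptable ungapped hit could have, floored to stay > 0
    stop_score = max(
        1.0, p.min_hit_len * (p.min_identity * p.match + (1 - p.min_identity) * p.mismatch)
    )
    masked = list(query)
    hits: List[LocalHit] = []
    for _ in range(p.max_hits):
        q = "".join(masked)
        best = None
        for strand, tseq in targets.items():
            alns = aligner.align(q, tseq)
            if alns.score < stop_score:
                continue
            if best is None or alns.score > best[0]:
                best = (alns.score, strand, alns[0], tseq)
        if best is None:
            break
        score, strand, aln, tseq = best
        matches, columns, qs, qe, ts, te = _alignment_stats(aln, q, tseq)
        if strand == "-":
            ts, te = len(tseq) - te, len(tseq) - ts
        hit = LocalHit(qs, qe, ts, te, strand, matches, columns, float(score))
        if columns > 0 and hit.identity >= 100 * p.min_identity and qe - qs >= p.min_hit_len:
            hits.append(hit)
        for i in range(qs, qe):
            masked[i] = "X"
    hits.sort(key=lambda h: h.query_start)
    return hits


@dataclass
class OrthologHit:
    """Per-species alignment summary of one SE."""

    se_id: str
    species: str
    aligned_fraction: float  # % of SE sequence covered by accepted hits
    identity: float  # % matched nucleotides over aligned columns
    hits: List[LocalHit] = field(default_factory=list)


def ortholog_se_search(
    se_id: str,
    species: str,
    se_seq: str,
    target_seq: str,
    params: Optional[LocalAlignParams] = None,
) -> Optional[OrthologHit]:
    """Align an SE to the intergenic sequence between syntenic partners.

    Returns ``None`` when no hit passes the filters; otherwise the
    aligned fraction (union of accepted query spans over SE length)
    and pooled identity over all accepted hits.
    """
    hits = local_align(se_seq, target_seq, params)
    if not hits:
        return None
    covered = 0
    last_end = -1
    for h in hits:  # hits sorted by query_start, query-disjoint by masking
        covered += h.query_end - max(h.query_start, last_end)
        last_end = max(last_end, h.query_end)
    matches = sum(h.matches for h in hits)
    columns = sum(h.columns for h in hits)
    return OrthologHit(
        se_id,
        species,
        aligned_fraction=100.0 * covered / len(se_seq),
        identity=100.0 * matches / columns,
        hits=hits,
    )


@dataclass
class SpanningPair:
    """The two genes flanking an intergenic SE, with per-species status."""

    se_id: str
    upstream_gene: str
    downstream_gene: str
    status: Dict[str, str] = field(default_factory=dict)

    def n_maintained(self) -> int:
        return sum(1 for s in self.status.values() if s == SYNTENIC_ADJACENT)


def se_spanning_pairs(
    ses: Sequence[SuperEnhancer], genes: Sequence[GeneModel]
) -> Tuple[List[SpanningPair], List[Tuple[str, str]]]:
    """Flanking gene pair per intergenic SE.

    Genic SEs and SEs at chromosome ends (missing a flank) are
    returned in the skipped list with a reason.
    """
    pairs: List[SpanningPair] = []
    skipped: List[Tuple[str, str]] = []
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.interval.start)
    for se in ses:
        if se.position_class != INTERGENIC:
            skipped.append((se.se_id, f"position_class={se.position_class}"))
            continue
        chrom_genes = by_chrom.get(se.interval.chrom, [])
        left = None
        right = None
        for g in chrom_genes:
            if g.interval.end <= se.interval.start:
                left = g
            elif g.interval.start >= se.interval.end and right is None:
                right = g
        if left is None or right is None:
            skipped.append((se.se_id, "chromosome end: missing flank"))
            continue
        pairs.append(SpanningPair(se.se_id, left.gene_id, right.gene_id))
    return pairs, skipped


def syntenic_status(
    pairs: Sequence[SpanningPair],
    synteny_tables: Dict[str, "pd.DataFrame"],
    target_annotations: Dict[str, Sequence[GeneModel]],
) -> List[SpanningPair]:
    """Fill per-species synteny status on each spanning pair.

    ``syntenic_adjacent``: both genes have partners in the species and
    the partners are adjacent (no gene between them) in the target
    annotation.  ``syntenic_nonadjacent``: partners exist but are
    separated.  ``absent``: at least one gene has no partner.
    """
    for species, table in synteny_tables.items():
        partner = dict(zip(table["query_gene"], table["target_gene"]))
        ann = target_annotations[species]
        rank: Dict[str, Tuple[str, int]] = {}
        by_chrom: Dict[str, List[GeneModel]] = {}
        for g in ann:
            by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: g.interval.start)
            for i, g in enumerate(gs):
                rank[g.gene_id] = (chrom, i)
        for pair in pairs:
            pa = partner.get(pair.upstream_gene)
            pb = partner.get(pair.downstream_gene)
            if pa is None or pb is None:
                pair.status[species] = ABSENT
                continue
            if pa not in rank or pb not in rank:
                raise KeyError(
                    f"synteny partner {pa if pa not in rank else pb!r} "
                    f"not in {species} annotation"
                )
            (ca, ia), (cb, ib) = rank[pa], rank[pb]
            if ca == cb and abs(ia - ib) == 1:
                pair.status[species] = SYNTENIC_ADJACENT
            else:
                pair.status[species] = SYNTENIC_NONADJACENT
    return list(pairs)


@dataclass
class RetentionResult:
    se_id: str
    species: str
    n_motifs_query: int
    n_retained: int

    @property
    def retention_rate(self) -> Optional[float]:
        if self.n_motifs_query == 0:
            return None  # undefined, not 0
        return 100.0 * self.n_retained / self.n_motifs_query


def motif_retention(
    se_id: str,
    species: str,
    query_motif_ids: Sequence[str],
    ortholog_motif_ids: Sequence[str],
) -> RetentionResult:
    """Share of query motifs whose motif id recurs in the ortholog.

    Presence anywhere within the orthologous aligned sequence counts;
    positional conservation is not required.
    """
    present = set(ortholog_motif_ids)
    query = list(query_motif_ids)
    retained = sum(1 for m in query if m in present)
    return RetentionResult(se_id, species, len(query), retained)


def conservation_report(
    pairs: Sequence[SpanningPair],
    hits: Dict[str, Dict[str, Optional[OrthologHit]]],
    ses: Sequence[SuperEnhancer],
    cns_intervals: Sequence[GenomicInterval] = (),
) -> dict:
    """Per-species conservation percentages and CNS containment.

    ``hits`` maps species → {se_id → OrthologHit or None} over the
    pairs with ``syntenic_adjacent`` status in that species.  The CNS
    containment denominator is the SEs spanned by a syntenic pair in
    at least one species; an SE contains a CNS when it overlaps one by
    >= 1 bp.
    """
    species_rows = {}
    for species in sorted(hits):
        eligible = [p for p in pairs if p.status.get(species) == SYNTENIC_ADJACENT]
        n_hit = sum(
            1 for p in eligible if hits[species].get(p.se_id) is not None
        )
        n = len(eligible)
        species_rows[species] = {
            "n_syntenic_pairs": n,
            "n_with_ortholog": n_hit,
            "percent": round(100 * n_hit / n) if n else None,
            "percent_unrounded": 100 * n_hit / n if n else None,
            "mean_identity": (
                float(np.mean([
                    hits[species][p.se_id].identity
                    for p in eligible
                    if hits[species].get(p.se_id) is not None
                ]))
                if n_hit
                else None
            ),
        }
    syntenic_se_ids = {
        p.se_id
        for p in pairs
        if any(s == SYNTENIC_ADJACENT for s in p.status.values())
    }
    se_by_id = {s.se_id: s for s in ses}
    n_cns = 0
    for se_id in syntenic_se_ids:
        se = se_by_id[se_id]
        if any(overlap_length(se.interval, c) >= 1 for c in cns_intervals):
            n_cns += 1
    n_syn = len(syntenic_se_ids)
    return {
        "per_species": species_rows,
        "n_ses_in_syntenic_pair": n_syn,
        "n_ses_with_cns": n_cns,
        "cns_percent": round(100 * n_cns / n_syn) if n_syn else None,
        "cns_percent_unrounded": 100 * n_cns / n_syn if n_syn else None,
    }


@dataclass
class SyntenyMaintenanceResult:
    percent_with: float
    percent_without: float
    p_value: float
    n_resamples: int
    capped: bool = False


def synteny_maintenance(
    pairs_with_se: Sequence[SpanningPair],
    pairs_without_se: Sequence[SpanningPair],
    min_species: int = 5,
    n_resamples: int = 1000,
    seed: int = 0,
) -> SyntenyMaintenanceResult:
    """Synteny-maintenance share of SE-spanning pairs vs a resampled null.

    A pair maintains synteny in a species when its status there is
    ``syntenic_adjacent``; the statistic is the share of pairs
    maintained in at least ``min_species`` species.  The null draws
    ``len(pairs_with_se)`` pairs (without replacement, capped at the
    pool size) from the without-SE pool ``n_resamples`` times; the
    add-one empirical p-value tests "greater".
    """
    rng = np.random.default_rng(seed)
    with_flags = np.array([p.n_maintained() >= min_species for p in pairs_with_se])
    pool_flags = np.array([p.n_maintained() >= min_species for p in pairs_without_se])
    percent_with = 100.0 * with_flags.mean()
    percent_without = 100.0 * pool_flags.mean() if len(pool_flags) else float("nan")
    draw = len(with_flags)
    capped = draw > len(pool_flags)
    draw = min(draw, len(pool_flags))
    extreme = 0
    for _ in range(n_resamples):
        idx = rng.choice(len(pool_flags), size=draw, replace=False)
        if 100.0 * pool_flags[idx].mean() >= percent_with:
            extreme += 1
    p = (1 + extreme) / (1 + n_resamples)
    return SyntenyMaintenanceResult(percent_with, percent_without, p, n_resamples, capped)
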