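"""Genomic-context statistics for SEs.

Covers four analyses: gene density in sliding windows with the SE
length subtracted from the denominator; TAD-membership fractions with
an empirical (permutation) enrichment test against size-matched random
nongenic regions; filtering and SE-gene linking of chromatin-loop
tables; and one-sided rank-sum comparison of cognate-gene expression.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval, merge_intervals, overlap_length
from .se import SuperEnhancer


@dataclass
class WindowDensity:
    window: GenomicInterval
    n_genes: int
    subtracted_length: int
    density: float  # genes per effective window; NaN when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.density)


def gene_density_windows(
    genes: Sequence[GeneModel],
    subtract_regions: Sequence[GenomicInterval],
    chrom_lengths: Dict[str, int],
    window_bp: int = 15_000,
    step_bp: int = 5_000,
) -> List[WindowDensity]:
    """Sliding-window gene density with region-length correction.

    density = window_bp * n_genes / (window_bp - subtracted_length),
    where ``subtracted_length`` is the bp of (pre-merged)
    ``subtract_regions`` inside the window — by default the SE set, so
    that large SEs do not depress the apparent gene density of their
    neighborhoods.  Genes count by >= 1 bp body overlap.  Windows
    fully covered by subtracted regions are flagged undefined (NaN).
    Only full-length windows are emitted.
    """
    sub = merge_intervals(subtract_regions, max_gap=0)
    sub_trees: Dict[str, IntervalTree] = {}
    for iv in sub:
        sub_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    gene_trees: Dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end
        )

    out: List[WindowDensity] = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        gt = gene_trees.get(chrom, IntervalTree())
        st = sub_trees.get(chrom, IntervalTree())
        for start in range(0, L - window_bp + 1, step_bp):
            end = start + window_bp
            w = GenomicInterval(chrom, start, end)
            n_genes = len(gt.overlap(start, end))
            sub_len = sum(
                min(h.end, end) - max(h.begin, start) for h in st.overlap(start, end)
            )
            if sub_len >= window_bp:
                dens = float("nan")
            else:
                dens = window_bp * n_genes / (window_bp - sub_len)
            out.append(WindowDensity(w, n_genes, sub_len, dens))
    return out


def fraction_within_tads(
    regions: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    rule: str = "containment",
    min_overlap_frac: float = 0.5,
) -> float:
    """Fraction of regions located within a TAD.

    ``rule='containment'`` (default) requires the region to lie fully
    inside at least one TAD; ``rule='overlap'`` accepts a fractional
    overlap of at least ``min_overlap_frac`` of the region length.
    """
    if not regions:
        raise ValueError("empty region list")
    trees: Dict[str, IntervalTree] = {}
    for t in tads:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    n_in = 0
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        if rule == "containment":
            if any(h.begin <= r.start and r.end <= h.end for h in tree.overlap(r.start, r.end)):
                n_in += 1
        elif rule == "overlap":
            ov = max(
                (min(h.end, r.end) - max(h.begin, r.start) for h in tree.overlap(r.start, r.end)),
                default=0,
            )
            if ov >= min_overlap_frac * r.length:
                n_in += 1
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return n_in / len(regions)


def sample_random_nongenic(
    chrom_lengths: Dict[str, int],
    genes: Sequence[GeneModel],
    size_list: Sequence[int],
    n_sets: int,
    seed: int,
) -> List[List[GenomicInterval]]:
    """Place size-matched random intervals in the nongenic complement.

    Each of the ``n_sets`` sets contains one interval per requested
    size, placed uniformly at random over all gene-disjoint positions
    genome-wide (exact enumeration of valid start positions, so no
    rejection loop is needed).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    merged_genes = merge_intervals([g.interval for g in genes], max_gap=0)
    gaps: List[Tuple[str, int, int]] = []  # (chrom, start, end) of nongenic runs
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merged_genes:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, L in sorted(chrom_lengths.items()):
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                gaps.append((chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < L:
            gaps.append((chrom, pos, L))

    sets: List[List[GenomicInterval]] = []
    for _ in range(n_sets):
        one = []
        for size in size_list:
            counts = np.array(
                [max(0, (e - s) - size + 1) for _, s, e in gaps], dtype=np.int64
            )
            total = int(counts.sum())
            if total == 0:
                raise ValueError(f"no nongenic placement for size {size}")
            r = int(rng.integers(0, total))
            idx = int(np.searchsorted(np.cumsum(counts), r, side="right"))
            chrom, s, _ = gaps[idx]
            offset = r - (int(np.cumsum(counts)[idx - 1]) if idx else 0)
            one.append(GenomicInterval(chrom, s + offset, s + offset + size))
        sets.append(one)
    return sets


@dataclass
class EnrichmentResult:
    observed_fraction: float
    null_fractions: List[float]
    p_value: float
    n_sets: int


def empirical_enrichment_test(
    observed_fraction: float,
    null_fractions: Sequence[float],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Add-one empirical p-value against a permutation null.

    p = (1 + #{null >= observed}) / (1 + n) for ``alternative='greater'``
    (mirrored with <= for 'less'), so p is never 0 and lies in (0, 1].
    """
    if len(null_fractions) == 0:
        raise ValueError("need at least one null value")
    null = np.asarray(null_fractions, dtype=float)
    if alternative == "greater":
        extreme = int(np.sum(null >= observed_fraction))
    elif alternative == "less":
        extreme = int(np.sum(null <= observed_fraction))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + extreme) / (1 + len(null))
    return EnrichmentResult(observed_fraction, list(map(float, null)), p, len(null))


def tad_enrichment(
    regions: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    chrom_lengths: Dict[str, int],
    genes: Sequence[GeneModel],
    n_sets: int = 1000,
    seed: int = 0,
    rule: str = "containment",
) -> EnrichmentResult:
    """TAD-membership enrichment vs size-matched random nongenic sets."""
    observed = fraction_within_tads(regions, tads, rule=rule)
    sizes = [r.length for r in regions]
    null_sets = sample_random_nongenic(chrom_lengths, genes, sizes, n_sets, seed)
    null = [fraction_within_tads(s, tads, rule=rule) for s in null_sets]
    return empirical_enrichment_test(observed, null, alternative="greater")


def filter_and_link_loops(
    loops: pd.DataFrame,
    ses: Sequence[SuperEnhancer],
    genes: Sequence[GeneModel],
    fdr_max: float = 1e-10,
    promoter_bp: int = 500,
) -> pd.DataFrame:
    """Retain significant loops and link SEs to genes through them.

    ``loops`` needs columns chrom, a1_start, a1_end, a2_start, a2_end,
    stat, fdr.  A row with fdr < ``fdr_max`` yields one output row
    (se_id, gene_id, stat) for every (SE, gene) pair where one anchor
    overlaps the SE and the other overlaps the gene body or its
    promoter window.
    """
    required = ["chrom", "a1_start", "a1_end", "a2_start", "a2_end", "stat", "fdr"]
    missing = [c for c in required if c not in loops.columns]
    if missing:
        raise ValueError(f"loop table missing columns {missing}")

    se_trees: Dict[str, IntervalTree] = {}
    for s in ses:
        se_trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, s.se_id
        )
    gene_trees: Dict[str, IntervalTree] = {}
    for g in genes:
        t = gene_trees.setdefault(g.interval.chrom, IntervalTree())
        t.addi(g.interval.start, g.interval.end, g.gene_id)
        w = g.promoter_window(promoter_bp)
        t.addi(w.start, w.end, g.gene_id)

    rows = []
    for i, row in enumerate(loops.itertuples(index=False)):
        try:
            fdr = float(row.fdr)
            anchors = (
                (row.chrom, int(row.a1_start), int(row.a1_end)),
                (row.chrom, int(row.a2_start), int(row.a2_end)),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed loop row {i}: {exc}") from exc
        if not fdr < fdr_max:
            continue
        for (ca, sa, ea), (cb, sb, eb) in (anchors, anchors[::-1]):
            se_hits = se_trees.get(ca, IntervalTree()).overlap(sa, ea)
            gene_hits = gene_trees.get(cb, IntervalTree()).overlap(sb, eb)
            for sh in se_hits:
                for gh in gene_hits:
                    rows.append((sh.data, gh.data, float(row.stat)))
    out = pd.DataFrame(rows, columns=["se_id", "gene_id", "stat"])
    return (
        out.drop_duplicates(subset=["se_id", "gene_id"])
        .sort_values(["se_id", "gene_id"])
        .reset_index(drop=True)
    )


def rank_sum_greater(a: Sequence[float], b: Sequence[float]) -> float:
    """One-sided Mann-Whitney p (alternative: a stochastically > b).

    Exact by enumeration of all group assignments when the combined
    sample size is <= 12 (handles ties, unlike the textbook exact
    tables); normal approximation with tie correction otherwise.
    All-tied input returns p = 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    pooled = a + b
    if len(set(pooled)) == 1:
        return 1.0
    if len(pooled) <= 12:
        u_obs = _u_statistic(a, b)
        n = len(pooled)
        k = len(a)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), k):
            sel = set(idx)
            pa = [pooled[i] for i in idx]
            pb = [pooled[i] for i in range(n) if i not in sel]
            if _u_statistic(pa, pb) >= u_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def compare_cognate_expression(
    expr: pd.DataFrame,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    per_tissue: bool = True,
) -> pd.Series:
    """Per-tissue one-sided rank-sum p-values (a > b) on an expression
    matrix (genes x tissues)."""
    ga = [g for g in genes_a if g in expr.index]
    gb = [g for g in genes_b if g in expr.index]
    if not ga or not gb:
        raise ValueError("both gene sets must be non-empty and present in the matrix")
    cols = expr.columns if per_tissue else [None]
    ps = {}
    for col in cols:
        if col is None:
            va = expr.loc[ga].to_numpy().ravel()
            vb = expr.loc[gb].to_numpy().ravel()
            ps["all"] = rank_sum_greater(va, vb)
        else:
            ps[col] = rank_sum_greater(expr.loc[ga, col], expr.loc[gb, col])
    return pd.Series(ps, name="p_value")
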