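"""TF occupancy of ACR classes and pairwise enrichment odds ratios.

An ACR counts as bound by a TF when more than half of its length
(strictly > ``min_coverage``) is covered by the union of that TF's
ChIP peaks.  Enrichment between two ACR classes is the log odds ratio
of per-class bound/unbound counts, one 2x2 table per TF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .atlas import ACR
from .core import GenomicInterval, merge_intervals
from .se import SuperEnhancer

CONSTITUENT = "constituent"


@dataclass
class TFPeakSet:
    tf_id: str
    intervals: List[GenomicInterval]


@dataclass
class ContingencyTable:
    """Bound/unbound counts for one TF across two ACR classes.

    a = class-A ACRs bound, b = class-A unbound, c = class-B bound,
    d = class-B unbound (class A plays the "constituent" slot).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency cell")


def acr_classes_with_constituents(
    acrs: Sequence[ACR], ses: Sequence[SuperEnhancer]
) -> pd.Series:
    """Three-way class per ACR: constituent / promoter / nonpromoter.

    Constituent ACRs (members of an SE) override their nonpromoter
    label; the remaining labels pass through.
    """
    constituent_ids = {c.acr_id for s in ses for c in s.constituents}
    labels = {}
    for a in acrs:
        if a.acr_id in constituent_ids:
            labels[a.acr_id] = CONSTITUENT
        else:
            labels[a.acr_id] = a.acr_class
    return pd.Series(labels, name="acr_class")


def tf_occupancy(
    acrs: Sequence[ACR],
    tf_sets: Sequence[TFPeakSet],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Boolean occupancy matrix (ACR x TF).

    Coverage uses the union of a TF's peaks (no double counting) and
    the bound call is strict: covered fraction must exceed
    ``min_coverage``.
    """
    if not 0 <= min_coverage < 1:
        raise ValueError("min_coverage must be in [0, 1)")
    acr_ids = [a.acr_id for a in acrs]
    mat = pd.DataFrame(
        False, index=pd.Index(acr_ids, name="acr_id"),
        columns=[t.tf_id for t in tf_sets], dtype=bool,
    )
    for tf in tf_sets:
        merged = merge_intervals(tf.intervals, max_gap=0)
        trees: Dict[str, IntervalTree] = {}
        for iv in merged:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for a in acrs:
            tree = trees.get(a.interval.chrom)
            if tree is None:
                continue
            cov = sum(
                min(h.end, a.interval.end) - max(h.begin, a.interval.start)
                for h in tree.overlap(a.interval.start, a.interval.end)
            )
            if cov / a.interval.length > min_coverage:
                mat.loc[a.acr_id, tf.tf_id] = True
    return mat


def tf_counts_per_acr(matrix: pd.DataFrame) -> pd.Series:
    """Number of distinct TFs bound per ACR (row sums)."""
    return matrix.sum(axis=1).rename("n_tfs")


def tf_odds_ratio(
    table: ContingencyTable, correction: str = "haldane"
) -> tuple:
    """(odds ratio, natural-log odds ratio) for a 2x2 table.

    With ``correction='haldane'`` 0.5 is added to every cell iff any
    cell is zero; with ``correction=None`` a zero in b or d raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if correction == "haldane" and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b == 0 or d == 0 or c == 0:
        raise ValueError("zero cell without correction")
    orr = (a / b) / (c / d)
    return orr, math.log(orr)


def enrichment_scan(
    matrix: pd.DataFrame,
    classes: pd.Series,
    class_a: str,
    class_b: str,
    correction: str = "haldane",
) -> pd.DataFrame:
    """Per-TF log odds ratio of class_a vs class_b binding, sorted.

    Output columns: tf_id, a, b, c, d, odds_ratio, log_odds_ratio,
    corrected; sorted by log-OR descending, ties by tf_id.
    """
    ids_a = classes.index[classes == class_a]
    ids_b = classes.index[classes == class_b]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"empty class among {class_a!r}/{class_b!r}")
    sub_a = matrix.loc[matrix.index.intersection(ids_a)]
    sub_b = matrix.loc[matrix.index.intersection(ids_b)]
    rows = []
    for tf in matrix.columns:
        a = int(sub_a[tf].sum())
        b = len(sub_a) - a
        c = int(sub_b[tf].sum())
        d = len(sub_b) - c
        t = ContingencyTable(a, b, c, d)
        orr, lor = tf_odds_ratio(t, correction=correction)
        rows.append((tf, a, b, c, d, orr, lor, 0 in (a, b, c, d)))
    out = pd.DataFrame(
        rows,
        columns=["tf_id", "a", "b", "c", "d", "odds_ratio", "log_odds_ratio", "corrected"],
    )
    return out.sort_values(
        ["log_odds_ratio", "tf_id"], ascending=[False, True]
    ).reset_index(drop=True)


def motif_catalog(
    ses: Sequence[SuperEnhancer], motif_hits: pd.DataFrame
) -> pd.DataFrame:
    """Motif hits intersected with SE spans (genome coordinates).

    ``motif_hits`` needs columns motif_id, chrom, start, end; strand
    and score pass through when present.  Returns one row per
    (SE, hit) with the per-SE distinct-motif count joined on.
    """
    trees: Dict[str, IntervalTree] = {}
    for s in ses:
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, s.se_id
        )
    rows = []
    for row in motif_hits.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for h in tree.overlap(int(row.start), int(row.end)):
            rows.append((h.data, row.motif_id, row.chrom, int(row.start), int(row.end)))
    out = pd.DataFrame(rows, columns=["se_id", "motif_id", "chrom", "start", "end"])
    counts = out.groupby("se_id")["motif_id"].nunique().rename("n_distinct_motifs")
    return out.merge(counts, on="se_id", how="left")
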