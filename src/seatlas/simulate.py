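"""Synthetic data generator with known truth for every pipeline stage.

Emulates, at desk scale, the inputs the analysis consumes: a random
genome with a non-overlapping gene annotation; per-tissue accessible
chromatin (planted intergenic SE clusters, background nonpromoter
ACRs, promoter peaks, and read-start tracks around each peak); TADs
enriched over the planted SEs; chromatin loops from SEs to cognate
promoters; TF ChIP peaks concentrated at constituent ACRs; literal
8-mer motif words embedded in SE sequence; per-species ortholog
panels at controlled substitution/indel divergence with synteny
breaks; and junction read-pair libraries for known insertion
genotypes.  Every stochastic choice flows from one seeded generator,
so emitted files are byte-stable for a fixed seed.

The defaults target the scale the published analysis describes,
shrunk to a 2 x 1-Mb genome: nonpromoter ACRs average ~400 bp,
promoter ACRs ~590 bp, planted SEs span >= 1.6 kb with 3-8
constituents separated by < 50-bp gaps, and background ACRs are kept
<= 1.2 kb and >= 60 bp apart so they cannot chain into SE-sized
clusters (planted SEs are well separated from background singletons).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .atlas import Sample
from .core import GeneModel, GenomeIndex, GenomicInterval, merge_intervals
from .peaks import Peak, ReadStartTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome & annotation
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 300
    gene_length_mu: float = math.log(2000.0)
    gene_length_sigma: float = 0.4
    min_intergenic: int = 1200
    # accessibility landscape
    n_samples: int = 6
    n_planted_ses: int = 20
    constituents_min: int = 3
    constituents_max: int = 8
    constituent_length_mu: float = math.log(400.0)
    constituent_length_sigma: float = 0.3
    intra_se_gap_min: int = 10
    intra_se_gap_max: int = 49
    min_planted_se_span: int = 1600
    n_background_acrs: int = 400
    background_length_mu: float = math.log(400.0)
    background_length_sigma: float = 0.35
    background_length_max: int = 1200
    background_separation: int = 60  # > 49 so backgrounds never chain
    promoter_peak_prob: float = 0.9
    promoter_peak_length_mu: float = math.log(590.0)
    promoter_peak_length_sigma: float = 0.25
    sample_support_prob: float = 0.7
    reads_per_peak: int = 80
    background_read_rate: float = 0.002  # reads per bp per sample
    # chromatin context
    tad_coverage: float = 0.25
    tad_enrichment: float = 2.0
    tad_length_min: int = 20_000
    tad_length_max: int = 60_000
    n_decoy_loops: int = 50
    # TF occupancy (rates per ACR class: constituent, promoter, background)
    n_tfs: int = 10
    n_enriched_tfs: int = 2
    enriched_rates: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    base_rate: float = 0.2
    # motifs
    n_motif_words: int = 12
    motif_length: int = 8
    motifs_per_se_min: int = 3
    motifs_per_se_max: int = 6
    # expression
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.0
    expression_shift_sd: float = 2.0  # shift of SE-cognate genes, in log-SD units
    # ortholog panel
    species_divergence: Dict[str, float] = field(
        default_factory=lambda: {
            "aly": 0.05, "bst": 0.15, "cru": 0.25, "aal": 0.32, "bra": 0.38,
        }
    )
    indel_fraction: float = 0.05  # indel rate as a fraction of the substitution rate
    se_synteny_break_prob: float = 0.2
    null_synteny_break_prob: float = 0.35
    ortholog_missing_prob: float = 0.02
    ortholog_pad: int = 150
    # conserved noncoding sequence annotation
    cns_prob: float = 0.75  # chance a planted SE carries a CNS interval
    cns_length: int = 200
    n_decoy_cns: int = 30
    # insertion libraries
    n_insertion_loci: int = 6
    insertion_element_length: int = 600
    insertion_flank: int = 200
    insertion_read_length: int = 50
    insertion_pairs_per_junction: int = 10
    insertion_noise_pairs: int = 2


@dataclass
class TruthSet:
    """Ground truth for every planted feature, keyed to emitted files."""

    acr_records: List[dict] = field(default_factory=list)
    planted_ses: List[dict] = field(default_factory=list)
    tad_membership: Dict[str, bool] = field(default_factory=dict)
    tf_rates: Dict[str, Dict[str, float]] = field(default_factory=dict)
    se_gene_links: List[Tuple[str, str]] = field(default_factory=list)
    cognate_genes: Dict[str, str] = field(default_factory=dict)
    synteny_status: Dict[str, Dict[str, str]] = field(default_factory=dict)
    species_divergence: Dict[str, float] = field(default_factory=dict)
    insertion_genotypes: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, GenomicInterval):
                return [o.chrom, int(o.start), int(o.end), o.strand]
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), sort_keys=True, indent=1, default=_default)


class _FreeSpace:
    """Uniform placement of fixed-length items into shrinking free gaps."""

    def __init__(self, gaps: List[GenomicInterval]):
        self.gaps = list(gaps)

    def place(self, length: int, margin: int, rng: np.random.Generator) -> GenomicInterval:
        need = length + 2 * margin
        weights = np.array(
            [max(0, g.length - need + 1) for g in self.gaps], dtype=np.int64
        )
        total = int(weights.sum())
        if total == 0:
            raise ValueError(f"no free space for item of length {length}")
        r = int(rng.integers(0, total))
        cum = np.cumsum(weights)
        idx = int(np.searchsorted(cum, r, side="right"))
        offset = r - (int(cum[idx - 1]) if idx else 0)
        gap = self.gaps[idx]
        start = gap.start + margin + offset
        placed = GenomicInterval(gap.chrom, start, start + length)
        # split the gap around the placed item (keeping the margin free-less)
        new = []
        if start - margin > gap.start:
            new.append(GenomicInterval(gap.chrom, gap.start, start - margin))
        if start + length + margin < gap.end:
            new.append(GenomicInterval(gap.chrom, start + length + margin, gap.end))
        self.gaps[idx : idx + 1] = new
        return placed


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_genome_and_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[Dict[str, np.ndarray], List[GeneModel]]:
    """Random genome plus a non-overlapping, stranded gene annotation.

    Genes are laid left to right per chromosome with Dirichlet-
    distributed intergenic gaps of at least ``min_intergenic`` bp;
    each has 1-5 exons.  Raises when the requested genes cannot fit.
    """
    sequences = {
        f"chr{i + 1}": _random_sequence(config.chromosome_length, rng)
        for i in range(config.n_chromosomes)
    }
    genes: List[GeneModel] = []
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    for ci, chrom in enumerate(sorted(sequences)):
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = np.clip(
            rng.lognormal(config.gene_length_mu, config.gene_length_sigma, size=k),
            500, 8000,
        ).astype(int)
        free = config.chromosome_length - int(lengths.sum()) - (k + 1) * config.min_intergenic
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes on {chrom}; lower n_genes or gene length"
            )
        gaps = config.min_intergenic + (free * rng.dirichlet(np.ones(k + 1)))
        pos = 0.0
        for gi in range(k):
            pos += gaps[gi]
            start = int(pos)
            end = start + int(lengths[gi])
            pos = float(end)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g{ci + 1:02d}_{gi + 1:04d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=_random_exons(chrom, start, end, rng),
                )
            )
    return sequences, genes


def _random_exons(chrom: str, start: int, end: int, rng) -> tuple:
    n_ex = int(rng.integers(1, 6))
    length = end - start
    n_parts = 2 * n_ex - 1
    if length < 30 * n_parts:
        n_ex, n_parts = 1, 1
    if n_ex == 1:
        return (GenomicInterval(chrom, start, end),)
    parts = (20 + (length - 20 * n_parts) * rng.dirichlet(np.ones(n_parts))).astype(int)
    parts[-1] += length - int(parts.sum())
    exons = []
    pos = start
    for i, p in enumerate(parts):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + int(p)))
        pos += int(p)
    # stretch the final exon to the gene end to absorb rounding
    last = exons[-1]
    exons[-1] = GenomicInterval(chrom, last.start, end)
    return tuple(exons)


def _forbidden_regions(genes: Sequence[GeneModel], upstream_bp: int = 500):
    ivs = [g.interval for g in genes] + [g.promoter_window(upstream_bp) for g in genes]
    return merge_intervals(ivs, max_gap=0)


def _free_gaps(
    chrom_lengths: Dict[str, int], blocked: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in blocked:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    gaps = []
    for chrom in sorted(chrom_lengths):
        pos = 0
        for iv in sorted(by_chrom.get(chrom, []), key=lambda x: x.start):
            if iv.start > pos:
                gaps.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < chrom_lengths[chrom]:
            gaps.append(GenomicInterval(chrom, pos, chrom_lengths[chrom]))
    return gaps


def plant_accessibility_landscape(
    config: SimulationConfig,
    chrom_lengths: Dict[str, int],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    truth: TruthSet,
) -> List[Sample]:
    """Plant SE clusters, background ACRs and promoter peaks; emit
    per-sample peak sets and read-start tracks.

    Constituent sets are redrawn until the cluster span reaches
    ``min_planted_se_span``, so every planted SE clears the 1.5-kb SE
    definition; background ACRs are capped below it and spaced so
    they cannot chain.
    """
    space = _FreeSpace(_free_gaps(chrom_lengths, _forbidden_regions(genes)))

    # --- planted SEs ---
    for si in range(config.n_planted_ses):
        # redraw until the span clears the SE definition and still fits
        # the largest remaining intergenic gap
        max_fit = max((g.length for g in space.gaps), default=0) - 400
        if max_fit < config.min_planted_se_span:
            raise ValueError(
                f"no intergenic gap can hold SE {si + 1}; "
                "lower n_planted_ses or n_genes"
            )
        for _ in range(200):
            n_c = int(rng.integers(config.constituents_min, config.constituents_max + 1))
            lens = np.clip(
                rng.lognormal(
                    config.constituent_length_mu,
                    config.constituent_length_sigma,
                    size=n_c,
                ),
                150, 900,
            ).astype(int)
            gaps = rng.integers(
                config.intra_se_gap_min, config.intra_se_gap_max + 1, size=n_c - 1
            )
            span = int(lens.sum() + gaps.sum())
            if config.min_planted_se_span <= span <= max_fit:
                break
        else:
            raise ValueError("could not draw an SE span above the minimum")
        placed = space.place(span, margin=200, rng=rng)
        constituents = []
        pos = placed.start
        for i in range(n_c):
            c = GenomicInterval(placed.chrom, pos, pos + int(lens[i]))
            constituents.append(c)
            pos = c.end + (int(gaps[i]) if i < n_c - 1 else 0)
        se_id = f"trueSE{si + 1:03d}"
        truth.planted_ses.append(
            {"se_id": se_id, "interval": placed, "constituents": constituents}
        )
        for c in constituents:
            truth.acr_records.append(
                {"interval": c, "acr_class": "constituent", "se_id": se_id}
            )

    # --- background nonpromoter ACRs ---
    for _ in range(config.n_background_acrs):
        length = int(
            min(
                config.background_length_max,
                max(100, rng.lognormal(
                    config.background_length_mu, config.background_length_sigma
                )),
            )
        )
        placed = space.place(length, margin=config.background_separation, rng=rng)
        truth.acr_records.append(
            {"interval": placed, "acr_class": "background", "se_id": None}
        )

    # --- promoter peaks ---
    for g in genes:
        if rng.random() >= config.promoter_peak_prob:
            continue
        length = int(
            np.clip(
                rng.lognormal(
                    config.promoter_peak_length_mu, config.promoter_peak_length_sigma
                ),
                200, 1500,
            )
        )
        # centered a little inside the promoter window so the overlap is robust
        if g.strand == "+":
            end = min(g.tss + 100, chrom_lengths[g.interval.chrom])
            start = max(0, end - length)
        else:
            start = max(0, g.tss - 100)
            end = min(start + length, chrom_lengths[g.interval.chrom])
        truth.acr_records.append(
            {
                "interval": GenomicInterval(g.interval.chrom, start, end),
                "acr_class": "promoter",
                "se_id": None,
            }
        )

    # --- per-sample support and reads ---
    samples = []
    n_rec = len(truth.acr_records)
    support = rng.random((n_rec, config.n_samples)) < config.sample_support_prob
    for i in range(n_rec):
        if not support[i].any():
            support[i, int(rng.integers(0, config.n_samples))] = True
    for sj in range(config.n_samples):
        sample_id = f"S{sj + 1:02d}"
        peaks = []
        reads: Dict[str, List[np.ndarray]] = {c: [] for c in chrom_lengths}
        for i, rec in enumerate(truth.acr_records):
            if not support[i, sj]:
                continue
            iv: GenomicInterval = rec["interval"]
            jit_s = max(0, iv.start + int(rng.integers(-20, 21)))
            jit_e = min(chrom_lengths[iv.chrom], iv.end + int(rng.integers(-20, 21)))
            if jit_e - jit_s < 50:
                jit_s, jit_e = iv.start, iv.end
            peaks.append(
                Peak(
                    GenomicInterval(iv.chrom, jit_s, jit_e),
                    summit=(jit_s + jit_e) // 2,
                    score=1.0,
                )
            )
            # uniform cut density across the open interval: flat plateau
            # with sharp edges, as DNase cuts within an accessible region
            starts = rng.uniform(iv.start, iv.end, size=config.reads_per_peak)
            reads[iv.chrom].append(
                np.clip(starts, 0, chrom_lengths[iv.chrom] - 1).astype(np.int64)
            )
        tracks = {}
        for chrom, L in sorted(chrom_lengths.items()):
            bg = rng.integers(0, L, size=int(config.background_read_rate * L))
            pos = np.concatenate([bg] + reads[chrom]) if reads[chrom] else bg
            tracks[chrom] = ReadStartTrack(chrom, pos, total_mapped_reads=len(pos))
        # whole-sample library size for sensitivity normalization
        total = sum(len(t.positions) for t in tracks.values())
        for t in tracks.values():
            t.total_mapped_reads = total
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        samples.append(Sample(sample_id, tissue=f"tissue{sj + 1}", peaks=peaks, tracks=tracks))
    return samples


def simulate_context(
    config: SimulationConfig,
    chrom_lengths: Dict[str, int],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    truth: TruthSet,
) -> Tuple[List[GenomicInterval], pd.DataFrame, Dict[str, List[GenomicInterval]], pd.DataFrame]:
    """TADs, loops, TF peaks and expression around the planted truth.

    Each planted SE is covered by a TAD with probability
    ``tad_coverage * tad_enrichment``; background TADs avoid SEs and
    top the genome-wide coverage up to ``tad_coverage``.  Loops join
    each planted SE to its cognate gene promoter at FDR << the
    retention cutoff; decoys fall above it.
    """
    genome_bp = sum(chrom_lengths.values())
    tads: List[GenomicInterval] = []
    covered = 0
    p_in = config.tad_coverage * config.tad_enrichment
    se_zones = []
    for rec in truth.planted_ses:
        iv: GenomicInterval = rec["interval"]
        se_zones.append(GenomicInterval(iv.chrom, max(0, iv.start - 500), iv.end + 500))
        if rng.random() < p_in:
            m1 = int(rng.integers(2000, 15000))
            m2 = int(rng.integers(2000, 15000))
            t = GenomicInterval(
                iv.chrom,
                max(0, iv.start - m1),
                min(chrom_lengths[iv.chrom], iv.end + m2),
            )
            tads.append(t)
            covered += t.length
            truth.tad_membership[rec["se_id"]] = True
        else:
            truth.tad_membership[rec["se_id"]] = False
    tad_space = _FreeSpace(
        _free_gaps(chrom_lengths, merge_intervals(se_zones + tads, max_gap=0))
    )
    target = int(config.tad_coverage * genome_bp)
    while covered < target:
        length = int(rng.integers(config.tad_length_min, config.tad_length_max))
        try:
            t = tad_space.place(length, margin=100, rng=rng)
        except ValueError:
            break
        tads.append(t)
        covered += t.length
    tads.sort(key=lambda t: (t.chrom, t.start))

    # --- loops ---
    from .core import interval_distance

    loop_rows = []
    res = 2000
    for rec in truth.planted_ses:
        iv = rec["interval"]
        cands = [
            (interval_distance(iv, g.interval), g)
            for g in genes
            if g.interval.chrom == iv.chrom
        ]
        cands = [(d, g) for d, g in cands if d is not None]
        cands.sort(key=lambda t: (t[0], t[1].gene_id))
        cognate = cands[0][1]
        truth.cognate_genes[rec["se_id"]] = cognate.gene_id
        truth.se_gene_links.append((rec["se_id"], cognate.gene_id))
        a1 = int(iv.midpoint // res) * res
        a2 = int(cognate.tss // res) * res
        loop_rows.append(
            (
                iv.chrom, a1, a1 + res, a2, a2 + res,
                float(10 + 90 * rng.random()),
                float(10.0 ** -(12 + 3 * rng.random())),
            )
        )
    for _ in range(config.n_decoy_loops):
        chrom = sorted(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
        L = chrom_lengths[chrom]
        a1 = int(rng.integers(0, L - res))
        a2 = int(rng.integers(0, L - res))
        loop_rows.append(
            (
                chrom, a1, a1 + res, a2, a2 + res,
                float(1 + 9 * rng.random()),
                float(10.0 ** (-9 * rng.random())),  # fdr in [1e-9, 1] >= cutoff
            )
        )
    loops = pd.DataFrame(
        loop_rows,
        columns=["chrom", "a1_start", "a1_end", "a2_start", "a2_end", "stat", "fdr"],
    )

    # --- TF peaks ---
    tf_peaks: Dict[str, List[GenomicInterval]] = {}
    class_map = {"constituent": 0, "promoter": 1, "background": 2}
    for ti in range(config.n_tfs):
        tf_id = f"TF{ti + 1:02d}"
        if ti < config.n_enriched_tfs:
            rates = config.enriched_rates
        else:
            rates = (config.base_rate,) * 3
        truth.tf_rates[tf_id] = {
            "constituent": rates[0], "promoter": rates[1], "background": rates[2],
        }
        ivs = []
        for rec in truth.acr_records:
            rate = rates[class_map[rec["acr_class"]]]
            if rng.random() < rate:
                iv = rec["interval"]
                ivs.append(
                    GenomicInterval(
                        iv.chrom,
                        max(0, iv.start - 20),
                        min(chrom_lengths[iv.chrom], iv.end + 20),
                    )
                )
        tf_peaks[tf_id] = ivs

    # --- expression ---
    cognate_set = set(truth.cognate_genes.values())
    tissues = [f"tissue{j + 1}" for j in range(config.n_samples)]
    values = {}
    for g in genes:
        mu = config.expression_log_mean
        if g.gene_id in cognate_set:
            mu += config.expression_shift_sd * config.expression_log_sd
        values[g.gene_id] = np.exp(
            rng.normal(mu, config.expression_log_sd, size=len(tissues))
        )
    expr = pd.DataFrame.from_dict(values, orient="index", columns=tissues)
    expr.index.name = "gene_id"
    return tads, loops, tf_peaks, expr


def embed_motifs(
    config: SimulationConfig,
    sequences: Dict[str, np.ndarray],
    rng: np.random.Generator,
    truth: TruthSet,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Write literal motif words into planted SE sequence.

    Returns the motif vocabulary (id → word) and a genome-coordinate
    hit table.  Words are embedded non-overlapping inside each SE
    span so retention is decidable downstream by exact string search.
    """
    words = {}
    while len(words) < config.n_motif_words:
        w = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=config.motif_length)
        )
        wid = f"M{len(words) + 1:02d}"
        if w not in words.values():
            words[wid] = w
    hit_rows = []
    wids = sorted(words)
    for rec in truth.planted_ses:
        iv: GenomicInterval = rec["interval"]
        k = int(rng.integers(config.motifs_per_se_min, config.motifs_per_se_max + 1))
        chosen = rng.choice(len(wids), size=k, replace=False)
        starts = np.sort(
            rng.choice(
                iv.length - config.motif_length,
                size=k,
                replace=False,
            )
        )
        # enforce non-overlap by spacing collisions out
        for j in range(1, k):
            if starts[j] < starts[j - 1] + config.motif_length + 2:
                starts[j] = starts[j - 1] + config.motif_length + 2
        for j, widx in enumerate(chosen):
            s = iv.start + int(starts[j])
            if s + config.motif_length > iv.end:
                continue
            wid = wids[int(widx)]
            word = words[wid]
            sequences[iv.chrom][s : s + config.motif_length] = np.frombuffer(
                word.encode(), dtype=np.uint8
            )
            hit_rows.append((wid, iv.chrom, s, s + config.motif_length, "+", 10.0))
    hits = pd.DataFrame(
        hit_rows, columns=["motif_id", "chrom", "start", "end", "strand", "score"]
    )
    return words, hits


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Substitute, delete and insert bases at the given per-bp rates."""
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r < sub_rate:
            choices = [b for b in bases if b != ch]
            out.append(choices[int(rng.integers(0, 3))])
        elif r < sub_rate + indel_rate / 2:
            continue  # deletion
        else:
            out.append(ch)
            if rng.random() < indel_rate / 2:
                out.append(bases[int(rng.integers(0, 4))])
    return "".join(out)


def simulate_ortholog_panel(
    config: SimulationConfig,
    sequences: Dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    motif_words: Dict[str, str],
    rng: np.random.Generator,
    truth: TruthSet,
) -> dict:
    """Per-species synteny tables, target annotations, ortholog
    intergenic sequences and motif-hit tables.

    Adjacent query gene pairs keep their adjacency in a species unless
    broken (an extra gene inserted between the partners); SE-spanning
    pairs break at ``se_synteny_break_prob`` and the rest at
    ``null_synteny_break_prob``.  For maintained SE pairs the target
    intergenic sequence is the SE sequence mutated at the species'
    planted substitution/indel rates, padded with random flanks.
    """
    truth.species_divergence = dict(config.species_divergence)
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.interval.start)

    # map adjacent gene pair -> planted SEs between them
    pair_ses: Dict[Tuple[str, str], List[dict]] = {}
    for rec in truth.planted_ses:
        iv = rec["interval"]
        gs = by_chrom[iv.chrom]
        left = None
        right = None
        for g in gs:
            if g.interval.end <= iv.start:
                left = g
            elif g.interval.start >= iv.end and right is None:
                right = g
        if left is not None and right is not None:
            pair_ses.setdefault((left.gene_id, right.gene_id), []).append(rec)

    panel = {
        "synteny_tables": {},
        "target_annotations": {},
        "ortholog_seqs": {},
        "ortholog_motifs": [],
    }
    se_flank_genes = set()
    for a, b in pair_ses:
        se_flank_genes.update((a, b))

    for species in sorted(config.species_divergence):
        sub_rate = config.species_divergence[species]
        indel_rate = sub_rate * config.indel_fraction
        truth.synteny_status[species] = {}
        syn_rows = []
        ann: List[GeneModel] = []
        seqs: Dict[str, str] = {}
        ins_counter = 0
        for chrom in sorted(by_chrom):
            gs = by_chrom[chrom]
            t_chrom = f"{species}_{chrom}"
            pos = 1000
            target_genes: List[Tuple[str, int, str]] = []  # (gene_id, length, strand)
            present: Dict[str, bool] = {}
            for g in gs:
                if g.gene_id in se_flank_genes:
                    present[g.gene_id] = True
                else:
                    present[g.gene_id] = rng.random() >= config.ortholog_missing_prob
            for gi, g in enumerate(gs):
                if present[g.gene_id]:
                    target_genes.append((f"{species}_{g.gene_id}", 1000, g.strand))
                    syn_rows.append((g.gene_id, f"{species}_{g.gene_id}", f"blk_{chrom}"))
                if gi + 1 < len(gs):
                    nxt = gs[gi + 1]
                    pair = (g.gene_id, nxt.gene_id)
                    is_se_pair = pair in pair_ses
                    break_p = (
                        config.se_synteny_break_prob
                        if is_se_pair
                        else config.null_synteny_break_prob
                    )
                    broken = rng.random() < break_p
                    if broken and present[g.gene_id] and present[nxt.gene_id]:
                        ins_counter += 1
                        target_genes.append((f"{species}_ins{ins_counter:04d}", 400, "+"))
                    if is_se_pair:
                        for rec in pair_ses[pair]:
                            se_id = rec["se_id"]
                            if not (present[g.gene_id] and present[nxt.gene_id]):
                                status = "absent"
                            elif broken:
                                status = "syntenic_nonadjacent"
                            else:
                                status = "syntenic_adjacent"
                            truth.synteny_status[species][se_id] = status
                            if status != "syntenic_adjacent":
                                continue
                            iv = rec["interval"]
                            se_seq = (
                                sequences[iv.chrom][iv.start : iv.end]
                                .tobytes()
                                .decode()
                            )
                            mutated = mutate_sequence(se_seq, sub_rate, indel_rate, rng)
                            pad1 = _random_sequence(config.ortholog_pad, rng).tobytes().decode()
                            pad2 = _random_sequence(config.ortholog_pad, rng).tobytes().decode()
                            seqs[se_id] = pad1 + mutated + pad2
                            for wid in sorted(motif_words):
                                word = motif_words[wid]
                                if word in mutated:
                                    panel["ortholog_motifs"].append(
                                        (species, se_id, wid)
                                    )
            for gid, length, strand in target_genes:
                ann.append(
                    GeneModel(
                        gene_id=gid,
                        interval=GenomicInterval(t_chrom, pos, pos + length, strand),
                        exons=(GenomicInterval(t_chrom, pos, pos + length),),
                    )
                )
                pos += length + 500
        panel["synteny_tables"][species] = pd.DataFrame(
            syn_rows, columns=["query_gene", "target_gene", "block_id"]
        )
        panel["target_annotations"][species] = ann
        panel["ortholog_seqs"][species] = seqs
    panel["ortholog_motifs"] = pd.DataFrame(
        panel["ortholog_motifs"], columns=["species", "se_id", "motif_id"]
    )
    return panel


def simulate_insertion_libraries(
    config: SimulationConfig,
    sequences: Dict[str, np.ndarray],
    rng: np.random.Generator,
    truth: TruthSet,
) -> dict:
    """Junction read-pair libraries for loci with known genotypes.

    Present loci yield pairs spanning the left and right joints only;
    absent loci span the cross joint only; a few noise pairs from
    random genome positions are mixed in and map to no junction.
    """
    from .core import GenomeIndex
    from .genotyping import InsertionLocus, JunctionSet, _revcomp, build_junctions

    chrom = sorted(sequences)[0]
    L = len(sequences[chrom])
    genome = GenomeIndex.from_sequences(
        {c: s.tobytes().decode() for c, s in sequences.items()}
    )
    f = config.insertion_flank
    rl = config.insertion_read_length
    loci = []
    libraries = {}
    for li in range(config.n_insertion_loci):
        locus_id = f"ins{li + 1:02d}"
        start = int(rng.integers(f + 1000, L - f - config.insertion_element_length - 1000))
        locus = InsertionLocus(
            locus_id, chrom, start, start + config.insertion_element_length, flank=f
        )
        element = genome.fetch(
            GenomicInterval(chrom, locus.insertion_start, locus.insertion_end)
        )
        junctions = build_junctions(genome, element, locus)
        genotype = "present" if li % 2 == 0 else "absent"
        truth.insertion_genotypes[locus_id] = genotype
        refs = (
            [junctions.left_joint, junctions.right_joint]
            if genotype == "present"
            else [junctions.cross_joint]
        )
        pairs = []
        for ref in refs:
            for _ in range(config.insertion_pairs_per_junction):
                u = int(rng.integers(0, f - rl + 1))
                v = int(rng.integers(f, 2 * f - rl + 1))
                pairs.append((ref[u : u + rl], _revcomp(ref[v : v + rl])))
        for _ in range(config.insertion_noise_pairs):
            u = int(rng.integers(0, L - rl))
            v = int(rng.integers(0, L - rl))
            pairs.append(
                (
                    sequences[chrom][u : u + rl].tobytes().decode(),
                    sequences[chrom][v : v + rl].tobytes().decode(),
                )
            )
        loci.append((locus, element))
        libraries[locus_id] = pairs
    return {"loci": loci, "libraries": libraries}


def simulate_cns(
    config: SimulationConfig,
    chrom_lengths: Dict[str, int],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    truth: TruthSet,
) -> List[GenomicInterval]:
    """Conserved-noncoding-sequence intervals: the central slice of a
    planted SE with probability ``cns_prob``, plus intergenic decoys."""
    cns = []
    for rec in truth.planted_ses:
        if rng.random() < config.cns_prob:
            iv: GenomicInterval = rec["interval"]
            mid = int(iv.midpoint)
            half = config.cns_length // 2
            cns.append(GenomicInterval(iv.chrom, mid - half, mid + half))
    space = _FreeSpace(_free_gaps(chrom_lengths, _forbidden_regions(genes)))
    for _ in range(config.n_decoy_cns):
        try:
            cns.append(space.place(config.cns_length, margin=50, rng=rng))
        except ValueError:
            break
    cns.sort(key=lambda c: (c.chrom, c.start))
    return cns


@dataclass
class SyntheticDataset:
    """All simulated inputs plus the truth tables, in memory."""

    config: SimulationConfig
    sequences: Dict[str, str]
    genome: GenomeIndex
    genes: List[GeneModel]
    samples: List[Sample]
    tads: List[GenomicInterval]
    loops: pd.DataFrame
    tf_peaks: Dict[str, List[GenomicInterval]]
    expression: pd.DataFrame
    motif_words: Dict[str, str]
    motif_hits: pd.DataFrame
    panel: dict
    cns: List[GenomicInterval]
    insertions: dict
    truth: TruthSet

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self.genome.lengths)


def simulate(config: Optional[SimulationConfig] = None) -> SyntheticDataset:
    """Run every generator stage in a fixed order from one seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    seq_arrays, genes = simulate_genome_and_annotation(config, rng)
    chrom_lengths = {c: len(s) for c, s in seq_arrays.items()}
    samples = plant_accessibility_landscape(config, chrom_lengths, genes, rng, truth)
    tads, loops, tf_peaks, expr = simulate_context(
        config, chrom_lengths, genes, rng, truth
    )
    words, motif_hits = embed_motifs(config, seq_arrays, rng, truth)
    panel = simulate_ortholog_panel(config, seq_arrays, genes, words, rng, truth)
    cns = simulate_cns(config, chrom_lengths, genes, rng, truth)
    insertions = simulate_insertion_libraries(config, seq_arrays, rng, truth)
    sequences = {c: s.tobytes().decode() for c, s in seq_arrays.items()}
    genome = GenomeIndex.from_sequences(sequences)
    return SyntheticDataset(
        config=config,
        sequences=sequences,
        genome=genome,
        genes=genes,
        samples=samples,
        tads=tads,
        loops=loops,
        tf_peaks=tf_peaks,
        expression=expr,
        motif_words=words,
        motif_hits=motif_hits,
        panel=panel,
        cns=cns,
        insertions=insertions,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str) -> None:
    """Emit the dataset as a self-contained directory of text files."""
    sio.ensure_dir(outdir)
    sio.write_fasta(os.path.join(outdir, "genome.fa"), ds.sequences)
    sio.write_gff3_genes(os.path.join(outdir, "genes.gff3"), ds.genes)
    sdir = sio.ensure_dir(os.path.join(outdir, "samples"))
    sheet = []
    for s in ds.samples:
        sheet.append((s.sample_id, s.tissue))
        sio.write_bed(
            os.path.join(sdir, f"{s.sample_id}.bed"),
            [
                {
                    "chrom": p.interval.chrom, "start": p.interval.start,
                    "end": p.interval.end, "name": f"{s.sample_id}_pk{i}",
                    "score": p.score,
                }
                for i, p in enumerate(s.peaks)
            ],
        )
        rows = []
        for chrom in sorted(s.tracks):
            for pos in s.tracks[chrom].positions:
                rows.append((chrom, int(pos)))
        pd.DataFrame(rows, columns=["chrom", "position"]).to_csv(
            os.path.join(sdir, f"{s.sample_id}.reads.tsv"), sep="\t", index=False
        )
    pd.DataFrame(sheet, columns=["sample_id", "tissue"]).to_csv(
        os.path.join(outdir, "sample_sheet.tsv"), sep="\t", index=False
    )
    sio.write_bed(
        os.path.join(outdir, "tads.bed"),
        [
            {"chrom": t.chrom, "start": t.start, "end": t.end, "name": f"tad{i}"}
            for i, t in enumerate(ds.tads)
        ],
    )
    sio.write_tsv(ds.loops, os.path.join(outdir, "loops.tsv"))
    tdir = sio.ensure_dir(os.path.join(outdir, "tf"))
    for tf_id in sorted(ds.tf_peaks):
        sio.write_bed(
            os.path.join(tdir, f"{tf_id}.bed"),
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "name": tf_id}
                for iv in ds.tf_peaks[tf_id]
            ],
        )
    sio.write_tsv(ds.motif_hits, os.path.join(outdir, "motifs.tsv"))
    ds.expression.reset_index().to_csv(
        os.path.join(outdir, "expression.tsv"), sep="\t", index=False
    )
    odir = sio.ensure_dir(os.path.join(outdir, "ortholog"))
    syn_frames = []
    for sp in sorted(ds.panel["synteny_tables"]):
        t = ds.panel["synteny_tables"][sp].copy()
        t.insert(0, "species", sp)
        syn_frames.append(t)
        sio.write_fasta(
            os.path.join(odir, f"{sp}.fa"), dict(sorted(ds.panel["ortholog_seqs"][sp].items()))
        )
        sio.write_gff3_genes(
            os.path.join(odir, f"{sp}.gff3"), ds.panel["target_annotations"][sp]
        )
    sio.write_tsv(pd.concat(syn_frames, ignore_index=True), os.path.join(outdir, "synteny.tsv"))
    sio.write_tsv(ds.panel["ortholog_motifs"], os.path.join(outdir, "ortholog_motifs.tsv"))
    sio.write_bed(
        os.path.join(outdir, "cns.bed"),
        [
            {"chrom": c.chrom, "start": c.start, "end": c.end, "name": f"cns{i}"}
            for i, c in enumerate(ds.cns)
        ],
    )
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(asdict(ds.config), fh, sort_keys=True, indent=1)
    idir = sio.ensure_dir(os.path.join(outdir, "insertions"))
    loci_rows = []
    for locus, element in ds.insertions["loci"]:
        loci_rows.append(
            (locus.locus_id, locus.chrom, locus.insertion_start, locus.insertion_end, locus.flank)
        )
        pd.DataFrame(
            [
                (f"{locus.locus_id}_rp{i}", m1, m2)
                for i, (m1, m2) in enumerate(ds.insertions["libraries"][locus.locus_id])
            ],
            columns=["pair_id", "mate1_seq", "mate2_seq"],
        ).to_csv(os.path.join(idir, f"{locus.locus_id}.reads.tsv"), sep="\t", index=False)
    pd.DataFrame(
        loci_rows, columns=["locus_id", "chrom", "insertion_start", "insertion_end", "flank"]
    ).to_csv(os.path.join(idir, "loci.tsv"), sep="\t", index=False)
    trdir = sio.ensure_dir(os.path.join(outdir, "truth"))
    with open(os.path.join(trdir, "truth.json"), "w") as fh:
        fh.write(ds.truth.to_json())
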