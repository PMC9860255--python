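"""End-to-end workflow: peak calling → atlas → SE calling → context →
TF enrichment → conservation → insertion genotyping → report.

The pipeline runs either on an in-memory :class:`~seatlas.simulate.
SyntheticDataset` or on a dataset directory produced by
``write_dataset`` (re-read through the package's format readers).
When truth tables are available, recovery metrics against the planted
features are added to the report.  Reports are plain dicts serialized
with sorted keys and no timestamps, so identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .atlas import (
    ACR,
    NONPROMOTER,
    PROMOTER,
    Sample,
    annotate_sensitivity,
    build_union_acrs,
    classify_acrs,
    promoter_fraction,
)
from .conservation import (
    SYNTENIC_ADJACENT,
    LocalAlignParams,
    OrthologHit,
    SpanningPair,
    conservation_report,
    motif_retention,
    ortholog_se_search,
    se_spanning_pairs,
    syntenic_status,
    synteny_maintenance,
)
from .context import (
    compare_cognate_expression,
    filter_and_link_loops,
    gene_density_windows,
    tad_enrichment,
)
from .core import GeneModel, GenomeIndex, GenomicInterval, overlap_length
from .genotyping import (
    InsertionLocus,
    build_junctions,
    classify_insertion,
    count_spanning_pairs,
)
from .peaks import PeakCallParams, call_sample_peaks
from .se import (
    INTERGENIC,
    AtlasSummary,
    SuperEnhancer,
    assign_cognate_gene,
    classify_se_position,
    cluster_nonpromoter_acrs,
    select_super_enhancers,
    summarize_atlas,
)
from .simulate import SimulationConfig, SyntheticDataset, TruthSet
from .tf import acr_classes_with_constituents, enrichment_scan, tf_counts_per_acr, tf_occupancy


@dataclass
class RunConfig:
    """Stage parameters for one pipeline run.

    ``se_length_threshold=None`` applies the top-quantile SE rule
    (the primary definition); a bp value switches to a fixed length
    cutoff, e.g. the 1.5-kb value the quantile resolves to at
    publication scale.
    """

    promoter_upstream: int = 500
    cluster_gap: int = 49
    top_fraction: float = 0.025
    se_length_threshold: Optional[int] = None
    fdr_target: float = 0.001
    n_null_reps: int = 100
    call_peaks_from_reads: bool = True
    kde_bandwidth: float = 60.0
    kde_grid_step: int = 10
    kde_threshold_fold: float = 2.5
    min_peak_length: int = 50
    tf_min_coverage: float = 0.5
    min_identity: float = 0.70
    min_hit_len: int = 30
    loop_fdr_max: float = 1e-10
    tad_n_sets: int = 1000
    maintenance_min_species: int = 4
    n_resamples: int = 1000
    insertion_min_pairs: int = 4
    junction_max_mismatches: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    acrs: List[ACR]
    clusters: list
    ses: List[SuperEnhancer]
    summary: AtlasSummary
    report: dict
    occupancy: Optional[pd.DataFrame] = None
    pairs: Optional[List[SpanningPair]] = None


def _call_or_load_peaks(ds: SyntheticDataset, cfg: RunConfig) -> List[Sample]:
    samples = []
    for i, s in enumerate(ds.samples):
        if cfg.call_peaks_from_reads and s.tracks:
            params = PeakCallParams(
                bandwidth=cfg.kde_bandwidth,
                grid_step=cfg.kde_grid_step,
                threshold_fold=cfg.kde_threshold_fold,
                min_peak_length=cfg.min_peak_length,
                fdr_target=cfg.fdr_target,
                n_null_reps=cfg.n_null_reps,
                seed=cfg.seed + 7919 * (i + 1),
            )
            peaks, _ = call_sample_peaks(s.tracks, ds.chrom_lengths, params)
            samples.append(Sample(s.sample_id, s.tissue, peaks, s.tracks))
        else:
            samples.append(s)
    return samples


def _match_fraction(
    queries: Sequence[GenomicInterval], references: Sequence[GenomicInterval]
) -> float:
    """Fraction of queries with >= 50% of their length covered by a
    single reference interval."""
    if not queries:
        return float("nan")
    n = 0
    for q in queries:
        for r in references:
            if overlap_length(q, r) >= 0.5 * q.length:
                n += 1
                break
    return n / len(queries)


def run_pipeline(ds: SyntheticDataset, cfg: Optional[RunConfig] = None) -> PipelineResult:
    """Execute every stage and assemble the report dict."""
    cfg = cfg or RunConfig()
    report: dict = {"config": dataclasses.asdict(cfg)}

    # --- peaks & atlas ---
    samples = _call_or_load_peaks(ds, cfg)
    acrs = build_union_acrs(samples)
    classify_acrs(acrs, ds.genes, upstream_bp=cfg.promoter_upstream)
    report["atlas"] = {
        "n_samples": len(samples),
        "n_acrs": len(acrs),
        "promoter_fraction": promoter_fraction(acrs),
        "mean_nonpromoter_length": float(
            np.mean([a.interval.length for a in acrs if a.acr_class == NONPROMOTER])
        ),
        "mean_promoter_length": float(
            np.mean([a.interval.length for a in acrs if a.acr_class == PROMOTER])
        ),
    }

    # --- SE calling ---
    clusters = cluster_nonpromoter_acrs(acrs, max_gap=cfg.cluster_gap)
    ses, threshold = select_super_enhancers(
        clusters,
        top_fraction=cfg.top_fraction,
        length_threshold=cfg.se_length_threshold,
    )
    for se in ses:
        assign_cognate_gene(se, ds.genes)
        classify_se_position(se, ds.genes)
    summary = summarize_atlas(acrs, clusters, ses, threshold)
    report["se"] = summary.to_dict()

    # --- truth recovery ---
    truth = ds.truth
    if truth is not None and truth.planted_ses:
        truth_ivs = [rec["interval"] for rec in truth.planted_ses]
        called_ivs = [s.interval for s in ses]
        report["recovery"] = {
            "recall": _match_fraction(truth_ivs, called_ivs),
            "precision": _match_fraction(called_ivs, truth_ivs),
            "n_planted": len(truth_ivs),
            "n_called": len(called_ivs),
        }

    # --- genomic context ---
    se_ivs = [s.interval for s in ses]
    enr = tad_enrichment(
        se_ivs, ds.tads, ds.chrom_lengths, ds.genes,
        n_sets=cfg.tad_n_sets, seed=cfg.seed + 13,
    )
    wins = gene_density_windows(ds.genes, se_ivs, ds.chrom_lengths)
    se_windows = [
        w for w in wins if any(overlap_length(w.window, iv) > 0 for iv in se_ivs)
    ]
    links = filter_and_link_loops(
        ds.loops, ses, ds.genes, fdr_max=cfg.loop_fdr_max,
        promoter_bp=cfg.promoter_upstream,
    )
    cognate = sorted({s.cognate_gene for s in ses if s.cognate_gene})
    others = sorted({g.gene_id for g in ds.genes} - set(cognate))
    expr_p = compare_cognate_expression(ds.expression, cognate, others)
    report["context"] = {
        "se_fraction_in_tads": enr.observed_fraction,
        "tad_enrichment_p": enr.p_value,
        "tad_null_mean": float(np.mean(enr.null_fractions)),
        "n_se_gene_links": int(len(links)),
        "mean_density_se_windows": float(
            np.nanmean([w.density for w in se_windows]) if se_windows else np.nan
        ),
        "mean_density_all_windows": float(np.nanmean([w.density for w in wins])),
        "expression_p_by_tissue": {k: float(v) for k, v in expr_p.items()},
    }
    if truth is not None and truth.se_gene_links:
        truth_links = set()
        for se_id, gene_id in truth.se_gene_links:
            for s in ses:
                if s.cognate_gene and overlap_length(
                    s.interval, _truth_interval(truth, se_id)
                ) > 0:
                    truth_links.add((s.se_id, gene_id))
        found = set(zip(links["se_id"], links["gene_id"]))
        report["context"]["link_recall"] = (
            len(found & truth_links) / len(truth_links) if truth_links else float("nan")
        )

    # --- TF occupancy ---
    from .tf import TFPeakSet

    tf_sets = [TFPeakSet(tf_id, ivs) for tf_id, ivs in sorted(ds.tf_peaks.items())]
    occupancy = tf_occupancy(acrs, tf_sets, min_coverage=cfg.tf_min_coverage)
    classes = acr_classes_with_constituents(acrs, ses)
    counts = tf_counts_per_acr(occupancy)
    scan = enrichment_scan(occupancy, classes, "constituent", "promoter")
    report["tf"] = {
        "mean_tfs_per_class": {
            cls: float(counts[classes[classes == cls].index].mean())
            for cls in sorted(classes.unique())
        },
        "top_enriched_tf": scan.iloc[0]["tf_id"],
        "top_log_odds_ratio": float(scan.iloc[0]["log_odds_ratio"]),
    }

    # --- conservation ---
    pairs, skipped = se_spanning_pairs(ses, ds.genes)
    syntenic_status(pairs, ds.panel["synteny_tables"], ds.panel["target_annotations"])
    se_to_truth = {}
    if truth is not None:
        for s in ses:
            best, best_ov = None, 0
            for rec in truth.planted_ses:
                ov = overlap_length(s.interval, rec["interval"])
                if ov > best_ov:
                    best, best_ov = rec["se_id"], ov
            if best is not None:
                se_to_truth[s.se_id] = best
    se_by_id = {s.se_id: s for s in ses}
    align_params = LocalAlignParams(
        min_identity=cfg.min_identity, min_hit_len=cfg.min_hit_len
    )
    hits: Dict[str, Dict[str, Optional[OrthologHit]]] = {}
    retention_rows = []
    qmotifs = _query_motifs_by_se(ses, ds.motif_hits)
    omot = ds.panel["ortholog_motifs"]
    for species in sorted(ds.panel["ortholog_seqs"]):
        hits[species] = {}
        seqs = ds.panel["ortholog_seqs"][species]
        for p in pairs:
            if p.status.get(species) != SYNTENIC_ADJACENT:
                continue
            tkey = se_to_truth.get(p.se_id, p.se_id)
            target = seqs.get(tkey)
            if target is None:
                hits[species][p.se_id] = None
                continue
            se = se_by_id[p.se_id]
            qseq = ds.genome.fetch(se.interval)
            hit = ortholog_se_search(p.se_id, species, qseq, target, align_params)
            hits[species][p.se_id] = hit
            if hit is not None:
                qm = qmotifs.get(p.se_id, [])
                om = omot[
                    (omot["species"] == species) & (omot["se_id"] == tkey)
                ]["motif_id"].tolist()
                r = motif_retention(p.se_id, species, qm, om)
                if r.retention_rate is not None:
                    retention_rows.append((species, p.se_id, r.retention_rate))
    cons = conservation_report(pairs, hits, ses, ds.cns)
    ret = pd.DataFrame(retention_rows, columns=["species", "se_id", "retention"])
    cons["mean_retention_by_species"] = {
        sp: float(v) for sp, v in ret.groupby("species")["retention"].mean().items()
    }

    null_pairs = _non_se_adjacent_pairs(ds.genes, ses)
    syntenic_status(
        null_pairs, ds.panel["synteny_tables"], ds.panel["target_annotations"]
    )
    maint = synteny_maintenance(
        pairs, null_pairs,
        min_species=cfg.maintenance_min_species,
        n_resamples=cfg.n_resamples,
        seed=cfg.seed + 17,
    )
    cons["synteny_maintenance"] = {
        "percent_with_se": maint.percent_with,
        "percent_without_se": maint.percent_without,
        "p_value": maint.p_value,
        "min_species": cfg.maintenance_min_species,
        "n_species": len(ds.panel["synteny_tables"]),
    }
    report["conservation"] = cons

    # --- insertion genotyping ---
    geno_rows = {}
    n_correct = 0
    n_eval = 0
    for locus, element in ds.insertions["loci"]:
        junctions = build_junctions(ds.genome, element, locus)
        evidence = count_spanning_pairs(
            ds.insertions["libraries"][locus.locus_id],
            junctions,
            max_mismatches=cfg.junction_max_mismatches,
        )
        call = classify_insertion(evidence, min_pairs=cfg.insertion_min_pairs)
        geno_rows[locus.locus_id] = {
            "call": call.call,
            "n_left": evidence.n_left,
            "n_right": evidence.n_right,
            "n_cross": evidence.n_cross,
        }
        if truth is not None and locus.locus_id in truth.insertion_genotypes:
            n_eval += 1
            if call.call == truth.insertion_genotypes[locus.locus_id]:
                n_correct += 1
    report["genotyping"] = {
        "calls": geno_rows,
        "accuracy": (n_correct / n_eval) if n_eval else float("nan"),
    }

    return PipelineResult(acrs, clusters, ses, summary, report, occupancy, pairs)


def _truth_interval(truth: TruthSet, se_id: str) -> GenomicInterval:
    for rec in truth.planted_ses:
        if rec["se_id"] == se_id:
            return rec["interval"]
    raise KeyError(se_id)


def _query_motifs_by_se(ses, motif_hits: pd.DataFrame) -> Dict[str, List[str]]:
    from .tf import motif_catalog

    if motif_hits is None or motif_hits.empty:
        return {}
    cat = motif_catalog(ses, motif_hits)
    return {
        se_id: grp["motif_id"].tolist() for se_id, grp in cat.groupby("se_id")
    }


def _non_se_adjacent_pairs(
    genes: Sequence[GeneModel], ses: Sequence[SuperEnhancer]
) -> List[SpanningPair]:
    """Consecutive gene pairs whose intergenic space holds no called SE."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    pairs = []
    k = 0
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: g.interval.start)
        for a, b in zip(gs, gs[1:]):
            if a.interval.end >= b.interval.start:
                continue
            gap = GenomicInterval(chrom, a.interval.end, b.interval.start)
            if any(overlap_length(gap, s.interval) > 0 for s in ses):
                continue
            k += 1
            pairs.append(SpanningPair(f"null{k:04d}", a.gene_id, b.gene_id))
    return pairs


def write_report(result: PipelineResult, outdir: str) -> str:
    """Write the report bundle (JSON + SE/ACR tables) deterministically."""
    sio.ensure_dir(outdir)
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(result.report, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
    se_rows = [
        {
            "se_id": s.se_id, "chrom": s.interval.chrom, "start": s.interval.start,
            "end": s.interval.end, "length": s.length,
            "n_constituents": s.n_constituents, "cognate_gene": s.cognate_gene,
            "cognate_distance": s.cognate_distance, "position_class": s.position_class,
            "intergenic_subclass": s.intergenic_subclass,
        }
        for s in result.ses
    ]
    sio.write_tsv(pd.DataFrame(se_rows), os.path.join(outdir, "super_enhancers.tsv"))
    acr_rows = [
        {
            "acr_id": a.acr_id, "chrom": a.interval.chrom, "start": a.interval.start,
            "end": a.interval.end, "acr_class": a.acr_class,
            "n_samples": len(a.supporting_samples),
        }
        for a in result.acrs
    ]
    sio.write_tsv(pd.DataFrame(acr_rows), os.path.join(outdir, "acrs.tsv"))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_dataset(directory: str) -> SyntheticDataset:
    """Re-read a ``write_dataset`` directory through the format readers."""
    from .peaks import Peak, ReadStartTrack

    d = str(directory)
    with open(os.path.join(d, "config.json")) as fh:
        raw = json.load(fh)
    raw["enriched_rates"] = tuple(raw["enriched_rates"])
    config = SimulationConfig(**raw)
    genome = GenomeIndex.from_fasta(os.path.join(d, "genome.fa"))
    sequences = {c: None for c in genome.lengths}
    genes = sio.read_gff3_genes(os.path.join(d, "genes.gff3"))
    sheet = sio.read_tsv(os.path.join(d, "sample_sheet.tsv"))
    samples = []
    for row in sheet.itertuples(index=False):
        peaks = [
            Peak(iv, summit=(iv.start + iv.end) // 2, score=1.0)
            for iv in sio.read_bed(os.path.join(d, "samples", f"{row.sample_id}.bed"))
        ]
        reads = sio.read_tsv(os.path.join(d, "samples", f"{row.sample_id}.reads.tsv"))
        total = len(reads)
        tracks = {
            chrom: ReadStartTrack(chrom, grp["position"].to_numpy(), total)
            for chrom, grp in reads.groupby("chrom")
        }
        samples.append(Sample(row.sample_id, row.tissue, peaks, tracks))
    tads = sio.read_bed(os.path.join(d, "tads.bed"))
    loops = sio.read_tsv(os.path.join(d, "loops.tsv"))
    tf_peaks = {}
    tdir = os.path.join(d, "tf")
    for fn in sorted(os.listdir(tdir)):
        tf_peaks[fn[:-4]] = sio.read_bed(os.path.join(tdir, fn))
    motif_hits = sio.read_tsv(os.path.join(d, "motifs.tsv"))
    expr = sio.read_tsv(os.path.join(d, "expression.tsv")).set_index("gene_id")
    syn = sio.read_tsv(os.path.join(d, "synteny.tsv"))
    panel = {
        "synteny_tables": {},
        "target_annotations": {},
        "ortholog_seqs": {},
        "ortholog_motifs": sio.read_tsv(os.path.join(d, "ortholog_motifs.tsv")),
    }
    import pyfaidx

    for sp, grp in syn.groupby("species"):
        panel["synteny_tables"][sp] = grp[
            ["query_gene", "target_gene", "block_id"]
        ].reset_index(drop=True)
        panel["target_annotations"][sp] = sio.read_gff3_genes(
            os.path.join(d, "ortholog", f"{sp}.gff3")
        )
        fa_path = os.path.join(d, "ortholog", f"{sp}.fa")
        seqs = {}
        if os.path.getsize(fa_path) > 0:
            fa = pyfaidx.Fasta(fa_path)
            seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
        panel["ortholog_seqs"][sp] = seqs
    cns = sio.read_bed(os.path.join(d, "cns.bed"))
    loci_df = sio.read_tsv(os.path.join(d, "insertions", "loci.tsv"))
    loci = []
    libraries = {}
    for row in loci_df.itertuples(index=False):
        locus = InsertionLocus(
            row.locus_id, row.chrom, int(row.insertion_start),
            int(row.insertion_end), int(row.flank),
        )
        element = genome.fetch(
            GenomicInterval(row.chrom, locus.insertion_start, locus.insertion_end)
        )
        loci.append((locus, element))
        reads = sio.read_tsv(os.path.join(d, "insertions", f"{row.locus_id}.reads.tsv"))
        libraries[row.locus_id] = list(zip(reads["mate1_seq"], reads["mate2_seq"]))
    truth = _load_truth(os.path.join(d, "truth", "truth.json"))
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
        motif_words={},
        motif_hits=motif_hits,
        panel=panel,
        cns=cns,
        insertions={"loci": loci, "libraries": libraries},
        truth=truth,
    )


def _load_truth(path: str) -> Optional[TruthSet]:
    if not os.path.exists(path):
        return None
    with open(path) as fh:
        raw = json.load(fh)

    def _iv(x):
        if isinstance(x, dict):
            return GenomicInterval(x["chrom"], x["start"], x["end"], x["strand"])
        return GenomicInterval(x[0], x[1], x[2], x[3])

    truth = TruthSet(
        acr_records=[
            {"interval": _iv(r["interval"]), "acr_class": r["acr_class"], "se_id": r["se_id"]}
            for r in raw["acr_records"]
        ],
        planted_ses=[
            {
                "se_id": r["se_id"],
                "interval": _iv(r["interval"]),
                "constituents": [_iv(c) for c in r["constituents"]],
            }
            for r in raw["planted_ses"]
        ],
        tad_membership=raw["tad_membership"],
        tf_rates=raw["tf_rates"],
        se_gene_links=[tuple(x) for x in raw["se_gene_links"]],
        cognate_genes=raw["cognate_genes"],
        synteny_status=raw["synteny_status"],
        species_divergence=raw["species_divergence"],
        insertion_genotypes=raw["insertion_genotypes"],
    )
    return truth
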