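"""Readers and writers for the standard formats at the package boundary.

GFF3 is 1-based closed and converted to the internal 0-based half-open
convention on read; BED is already half-open.  All tabular outputs are
TSV with a header line.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Optional

import pandas as pd

from .core import GeneModel, GenomicInterval

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals (name/score columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(path, rows: Iterable[dict]) -> None:
    """Write BED6; each row is a dict with at least chrom/start/end."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(r.get(c, "." if c in ("name", "strand") else 0))
                    for c in BED6_COLUMNS
                )
                + "\n"
            )


def read_gff3_genes(path) -> List[GeneModel]:
    """Parse gene models (gene/mRNA/exon features) from a GFF3 file.

    Exons are attached through an mRNA child when present, else
    directly to the gene; when a gene has several transcripts the
    union of their exons is used (merged where overlapping).  Raises
    ``ValueError`` with the offending line number on malformed rows.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            force=True,
        )
    except Exception as exc:  # gffutils wraps line info in the message
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc

    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id} in {path} is unstranded")
        exon_ivs = []
        for ex in db.children(g, featuretype="exon"):
            exon_ivs.append((ex.start - 1, ex.end))
        if not exon_ivs:
            exon_ivs = [(g.start - 1, g.end)]
        # merge overlapping exons across transcripts
        exon_ivs.sort()
        merged = []
        for s, e in exon_ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        chrom = g.seqid
        genes.append(
            GeneModel(
                gene_id=g.id,
                interval=GenomicInterval(chrom, g.start - 1, g.end, g.strand),
                exons=tuple(GenomicInterval(chrom, s, e) for s, e in merged),
            )
        )
    genes.sort(key=lambda gm: (gm.interval.chrom, gm.interval.start, gm.gene_id))
    return genes


def write_gff3_genes(path, genes: Iterable[GeneModel]) -> None:
    """Write gene models as gene/mRNA/exon rows (0-based → 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            base = (iv.chrom, "seatlas", iv.start + 1, iv.end, ".", iv.strand, ".")
            fh.write(
                "\t".join(map(str, base[:2] + ("gene",) + base[2:]))
                + f"\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                "\t".join(map(str, base[:2] + ("mRNA",) + base[2:]))
                + f"\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{iv.chrom}\tseatlas\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )


def write_fasta(path, sequences: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
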