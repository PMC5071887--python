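"""Small-format readers and writers shared across pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .comut import GeneClusterSet
from .errors import FormatError
from .hic import BackgroundCurve


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write BED6: chromStart is the 0-based TSS, name is the gene id."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.tss) - 1}\t{int(row.end)}\t"
                f"{row.gene_id}\t0\t{row.strand}\n"
            )


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 gene annotation; TSS is chromStart + 1 on the + strand."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = parts[:6]
            tss = int(start) + 1 if strand != "-" else int(end)
            rows.append((name, chrom, int(start) + 1, int(end), tss, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "tss", "strand"])
    if df["gene_id"].duplicated().any():
        raise FormatError(f"duplicate gene ids in {path}")
    return df


def write_background_curve(bg: BackgroundCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("d\tmean\tn\n")
        for d, (v, n) in enumerate(zip(bg.values, bg.counts)):
            if n > 0:
                fh.write(f"{d}\t{v:.10g}\t{n}\n")


def write_clusters_tsv(cs: GeneClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\n")
        for k, cluster in enumerate(cs.clusters):
            for g in cluster:
                fh.write(f"{cs.provenance}{k:04d}\t{g}\n")


def read_clusters_tsv(path: str | Path, provenance: str) -> GeneClusterSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters: dict[str, list[str]] = {}
    for cid, gid in zip(df["cluster_id"], df["gene_id"]):
        clusters.setdefault(cid, []).append(gid)
    return GeneClusterSet(
        clusters=[clusters[c] for c in sorted(clusters)], provenance=provenance
    )


def write_sch_table(schs: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sch_id\tchrom\tgene_id\tdb_cluster\thic_cluster\n")
        for s in schs:
            for g in s.gene_ids:
                fh.write(
                    f"{s.sch_id}\t{s.chrom}\t{g}\t{s.source_db_cluster}\t"
                    f"{s.source_hic_cluster}\n"
                )
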