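"""Intra-chromosomal Hi-C contact-matrix processing.

Implements the distance backgrounds, gene-pair contact lookups, the
diagonal (distance) normalization A' = A / b_overall(d), the Pearson
correlation matrix C over columns of A', and hierarchical spatial gene
clustering on 1 - C, plus the paired proximity test of co-mutated gene
pairs against their distance-matched backgrounds.

Bins are 0-based; a gene's bin is floor((TSS - 1) / bin_size).  Masked bins
(fully missing columns in the source data) propagate as NaN and are
excluded from every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .comut import GeneClusterSet
from .errors import AnalysisError, FormatError

log = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact matrix with a missing-bin mask."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    mask: np.ndarray  # True where the bin (whole column) is missing

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError("contact matrix must be square")
        if self.mask.shape != (m.shape[0],):
            raise FormatError("mask length must equal n_bins")


@dataclass
class BackgroundCurve:
    """Mean contact frequency per linear bin distance d.

    ``values[d]`` is NaN where no unmasked entry exists at that distance;
    ``counts[d]`` records how many entries contributed.
    """

    chrom: str
    kind: str  # "overall" | "gene-level"
    values: np.ndarray
    counts: np.ndarray

    def at(self, d: int) -> float:
        if d < 0 or d >= len(self.values):
            return float("nan")
        return float(self.values[d])


@dataclass
class NormalizedMatrix:
    """Distance-normalized matrix A' and (optionally) its PCC matrix C."""

    chrom: str
    bin_size: int
    aprime: np.ndarray
    mask: np.ndarray
    pcc: np.ndarray | None = None
    pcc_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# I/O

def read_contact_matrix(
    path: str | Path,
    fmt: str = "dense",
    chrom: str = "chr1",
    n_bins: int | None = None,
    bin_size: int = 40_000,
) -> ContactMatrix:
    """Read a dense TSV or COO-triple TSV contact matrix.

    Dense input must be symmetric; NaN cells mark missing data and a fully
    NaN column is masked.  COO triples (bin_i, bin_j, count) are mirrored;
    bins that never occur in any triple are masked.
    """
    if fmt == "dense":
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        if mat.shape[0] != mat.shape[1]:
            raise FormatError(f"dense matrix in {path} is not square")
        if n_bins is not None and mat.shape[0] != n_bins:
            raise FormatError(f"expected {n_bins} bins, found {mat.shape[0]}")
        finite = np.isfinite(mat)
        if not np.allclose(
            np.where(finite, mat, 0.0), np.where(finite.T, mat.T, 0.0), equal_nan=True
        ) or not (finite == finite.T).all():
            raise FormatError(f"dense matrix in {path} is not symmetric")
        if np.nanmin(mat) < 0 if finite.any() else False:
            raise FormatError("negative contact frequency")
        mask = ~finite.any(axis=0)
        mat = mat.copy()
        mat[:, mask] = np.nan
        mat[mask, :] = np.nan
        return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=mat, mask=mask)
    if fmt == "coo":
        if n_bins is None:
            raise FormatError("COO input requires n_bins")
        tri = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["i", "j", "count"],
        )
        mat = np.zeros((n_bins, n_bins))
        seen = np.zeros(n_bins, dtype=bool)
        for i, j, c in tri.itertuples(index=False):
            i, j = int(i), int(j)
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise FormatError(f"bin index out of range in {path}: ({i},{j})")
            if c < 0:
                raise FormatError(f"negative count in {path}")
            mat[i, j] = c
            mat[j, i] = c
            seen[i] = seen[j] = True
        mask = ~seen
        mat[:, mask] = np.nan
        mat[mask, :] = np.nan
        return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=mat, mask=mask)
    raise FormatError(f"unknown contact-matrix format {fmt!r}")


def write_contact_matrix(cm: ContactMatrix, path: str | Path, fmt: str = "dense") -> None:
    if fmt == "dense":
        np.savetxt(path, cm.matrix, delimiter="\t", fmt="%.10g")
        return
    if fmt == "coo":
        with open(path, "w") as fh:
            iu, ju = np.triu_indices(cm.n_bins)
            for i, j in zip(iu, ju):
                v = cm.matrix[i, j]
                if np.isfinite(v) and v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")
        return
    raise FormatError(f"unknown contact-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# Backgrounds

def overall_background(cm: ContactMatrix) -> BackgroundCurve:
    """Mean contact frequency of every d-th off-diagonal (d = 0 included)."""
    n = cm.n_bins
    values = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    m = cm.matrix
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        ok = np.isfinite(diag)
        counts[d] = int(ok.sum())
        if counts[d]:
            values[d] = float(diag[ok].mean())
    return BackgroundCurve(chrom=cm.chrom, kind="overall", values=values, counts=counts)


def gene_bins(annotation: pd.DataFrame, contact_maps: dict[str, ContactMatrix]) -> dict:
    """Map gene id -> (chrom, bin) for genes on chromosomes with Hi-C data.

    Genes whose TSS falls on a masked bin are omitted.
    """
    out: dict[str, tuple[str, int]] = {}
    for row in annotation.itertuples(index=False):
        chrom = row.chrom
        cm = contact_maps.get(chrom)
        if cm is None:
            continue
        b = (int(row.tss) - 1) // cm.bin_size
        if 0 <= b < cm.n_bins and not cm.mask[b]:
            out[row.gene_id] = (chrom, b)
    return out


def gene_level_background(
    cm: ContactMatrix, annotation: pd.DataFrame
) -> BackgroundCurve:
    """Distance background restricted to bin pairs that carry gene TSS pairs.

    Every (ordered by distance) pair of genes on the chromosome contributes
    its bin-pair entry; the same bin pair contributes once per gene pair.
    """
    ann = annotation[annotation["chrom"] == cm.chrom]
    bins = ((ann["tss"].to_numpy(int) - 1) // cm.bin_size).astype(int)
    bins = bins[(bins >= 0) & (bins < cm.n_bins)]
    bins = bins[~cm.mask[bins]]
    n = cm.n_bins
    values = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    if len(bins) < 2:
        log.warning("gene-level background on %s: fewer than 2 usable genes", cm.chrom)
        return BackgroundCurve(cm.chrom, "gene-level", values, counts)
    iu, ju = np.triu_indices(len(bins))  # includes d = 0 (same-bin gene pairs)
    keep = iu < ju
    bi, bj = bins[iu[keep]], bins[ju[keep]]
    d = np.abs(bi - bj)
    v = cm.matrix[bi, bj]
    ok = np.isfinite(v)
    d, v = d[ok], v[ok]
    sums = np.bincount(d, weights=v, minlength=n)
    cnts = np.bincount(d, minlength=n)
    nz = cnts > 0
    values[nz] = sums[nz] / cnts[nz]
    counts[:] = cnts
    return BackgroundCurve(cm.chrom, "gene-level", values, counts)


def gene_pair_contact(
    cm: ContactMatrix,
    annotation: pd.DataFrame,
    g1: str,
    g2: str,
) -> tuple[float, int]:
    """Contact frequency and bin distance of a same-chromosome gene pair.

    Returns (NaN, d) when either bin is masked.  Raises if either gene is
    not annotated on ``cm.chrom``.
    """
    ann = annotation.set_index("gene_id")
    for g in (g1, g2):
        if g not in ann.index:
            raise AnalysisError(f"gene {g} missing from annotation")
        if ann.loc[g, "chrom"] != cm.chrom:
            raise AnalysisError(
                f"gene {g} is on {ann.loc[g, 'chrom']}, not {cm.chrom}: "
                "inter-chromosomal pairs are not supported"
            )
    b1 = (int(ann.loc[g1, "tss"]) - 1) // cm.bin_size
    b2 = (int(ann.loc[g2, "tss"]) - 1) // cm.bin_size
    d = abs(b1 - b2)
    if cm.mask[b1] or cm.mask[b2]:
        return float("nan"), d
    return float(cm.matrix[b1, b2]), d


# ---------------------------------------------------------------------------
# Proximity test (co-mutated pairs vs backgrounds)

@dataclass
class ProximityReport:
    """Paired comparison of co-mutated pair contacts against backgrounds."""

    n_pairs: int
    comut_values: np.ndarray
    overall_values: np.ndarray
    gene_level_values: np.ndarray
    p_vs_overall: float
    p_vs_gene_level: float
    t_vs_overall: float
    t_vs_gene_level: float

    @property
    def mean_comut(self) -> float:
        return float(self.comut_values.mean())

    @property
    def mean_overall(self) -> float:
        return float(self.overall_values.mean())

    @property
    def mean_gene_level(self) -> float:
        return float(self.gene_level_values.mean())


def proximity_test(
    comut_pairs: Sequence[tuple[str, str]],
    contact_maps: dict[str, ContactMatrix],
    annotation: pd.DataFrame,
    backgrounds: dict[str, tuple[BackgroundCurve, BackgroundCurve]] | None = None,
) -> ProximityReport:
    """Paired t-test of co-mutated gene-pair contacts vs distance backgrounds.

    Each same-chromosome co-mutated pair contributes the triple
    (pair contact, b_overall(d), b_gene(d)) for its own bin distance d;
    the two paired two-sided t-tests compare the pair contacts to each
    background.  Cross-chromosome pairs and pairs touching masked bins are
    skipped.
    """
    if backgrounds is None:
        backgrounds = {
            chrom: (overall_background(cm), gene_level_background(cm, annotation))
            for chrom, cm in contact_maps.items()
        }
    info = gene_bins(annotation, contact_maps)
    comut, b_ov, b_gl = [], [], []
    for g1, g2 in comut_pairs:
        if g1 not in info or g2 not in info:
            continue
        c1, bin1 = info[g1]
        c2, bin2 = info[g2]
        if c1 != c2:
            continue
        cm = contact_maps[c1]
        v = cm.matrix[bin1, bin2]
        d = abs(bin1 - bin2)
        ov = backgrounds[c1][0].at(d)
        gl = backgrounds[c1][1].at(d)
        if np.isfinite(v) and np.isfinite(ov) and np.isfinite(gl):
            comut.append(v)
            b_ov.append(ov)
            b_gl.append(gl)
    if len(comut) < 2:
        raise AnalysisError(
            f"proximity test needs >= 2 usable same-chromosome pairs, got {len(comut)}"
        )
    comut_a = np.asarray(comut)
    ov_a = np.asarray(b_ov)
    gl_a = np.asarray(b_gl)

    def _paired(x, y):
        if np.allclose(x, y):
            return 0.0, 1.0
        t, p = stats.ttest_rel(x, y)
        return float(t), float(p)

    t_ov, p_ov = _paired(comut_a, ov_a)
    t_gl, p_gl = _paired(comut_a, gl_a)
    return ProximityReport(
        n_pairs=len(comut),
        comut_values=comut_a,
        overall_values=ov_a,
        gene_level_values=gl_a,
        p_vs_overall=p_ov,
        p_vs_gene_level=p_gl,
        t_vs_overall=t_ov,
        t_vs_gene_level=t_gl,
    )


# ---------------------------------------------------------------------------
# Normalization, correlation, spatial clustering

def diagonal_normalize(cm: ContactMatrix, bg: BackgroundCurve | None = None) -> NormalizedMatrix:
    """Divide every entry by the mean of its own off-diagonal.

    Where b_overall(d) is defined and positive, a'_ij = a_ij / b_overall(d);
    entries on masked bins or undefined distances stay NaN.  Every defined
    off-diagonal of A' has mean exactly 1 by construction.
    """
    if bg is None:
        bg = overall_background(cm)
    n = cm.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    denom = bg.values[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        aprime = np.where(denom > 0, cm.matrix / denom, np.nan)
        # an all-zero off-diagonal normalizes to all zeros, not NaN
        zero_diag = (denom == 0) & np.isfinite(cm.matrix)
        aprime[zero_diag] = 0.0
    return NormalizedMatrix(
        chrom=cm.chrom, bin_size=cm.bin_size, aprime=aprime, mask=cm.mask.copy()
    )


def pcc_matrix(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Pearson correlation between columns of A' (pairwise complete).

    Fully masked bins stay masked; unmasked columns with zero variance on
    the complete rows are additionally masked in C.  The diagonal of C is 1
    on usable bins.
    """
    valid = ~nm.mask
    if valid.sum() < 3:
        raise AnalysisError("PCC matrix needs at least 3 usable bins")
    sub = nm.aprime[np.ix_(valid, valid)]
    # masked bins are whole rows/columns of NaN, so pairwise-complete
    # correlation over unmasked columns reduces to complete rows here;
    # any residual NaN rows (undefined distances) are dropped.
    row_ok = np.isfinite(sub).all(axis=1)
    sub = sub[row_ok]
    if sub.shape[0] < 2:
        raise AnalysisError("fewer than 2 complete observations for correlation")
    sd = sub.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr[degenerate, degenerate] = np.nan
    n = nm.aprime.shape[0]
    full = np.full((n, n), np.nan)
    vi = np.flatnonzero(valid)
    full[np.ix_(vi, vi)] = corr
    pcc_mask = nm.mask.copy()
    pcc_mask[vi[degenerate]] = True
    return NormalizedMatrix(
        chrom=nm.chrom,
        bin_size=nm.bin_size,
        aprime=nm.aprime,
        mask=nm.mask,
        pcc=full,
        pcc_mask=pcc_mask,
    )


def hic_cluster(
    nm: NormalizedMatrix,
    annotation: pd.DataFrame,
    cutoff_policy: str = "noise",
    cutoff_value: float | None = None,
    noise_z: float = 3.0,
) -> GeneClusterSet:
    """Agglomerative (average-linkage) spatial clustering of genes.

    Gene-pair distance is 1 - c_{bin(g1), bin(g2)} from the PCC matrix.
    ``cutoff_policy``:

    * ``"noise"`` (default) — cut the tree at 1 - noise_z / sqrt(n - 3),
      i.e. merge only correlations ``noise_z`` standard errors above the
      sampling noise of a null Pearson coefficient estimated from n
      complete observations (Fisher approximation).  Scale-aware and
      conservative: chance correlations between unrelated loci rarely
      survive.
    * ``"mean"`` — cut at the mean pairwise distance of the condensed
      matrix (merges roughly half the mass; coarse).
    * ``"constant"`` — cut at ``cutoff_value``.

    Genes on masked bins are excluded and reported in ``excluded``.
    """
    if nm.pcc is None or nm.pcc_mask is None:
        raise AnalysisError("run pcc_matrix before hic_cluster")
    ann = annotation[annotation["chrom"] == nm.chrom]
    ann = ann.sort_values(["tss", "gene_id"], kind="mergesort")
    genes, bins, excluded = [], [], []
    for row in ann.itertuples(index=False):
        b = (int(row.tss) - 1) // nm.bin_size
        if 0 <= b < nm.aprime.shape[0] and not nm.pcc_mask[b]:
            genes.append(row.gene_id)
            bins.append(b)
        else:
            excluded.append(row.gene_id)
    if not genes:
        log.warning("hic_cluster on %s: no usable genes", nm.chrom)
        return GeneClusterSet(clusters=[], provenance="HiC", excluded=excluded)
    if len(genes) == 1:
        return GeneClusterSet(clusters=[[genes[0]]], provenance="HiC", excluded=excluded)
    bins_a = np.array(bins)
    dist = 1.0 - nm.pcc[np.ix_(bins_a, bins_a)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    if cutoff_policy == "noise":
        n_obs = int((~nm.pcc_mask).sum())
        cut = 1.0 - noise_z / np.sqrt(max(n_obs - 3, 1))
        cut = float(np.clip(cut, 0.05, 1.0))
    elif cutoff_policy == "mean":
        cut = float(condensed.mean())
    elif cutoff_policy == "constant":
        if cutoff_value is None:
            raise AnalysisError("cutoff_policy 'constant' needs cutoff_value")
        cut = float(cutoff_value)
    else:
        raise AnalysisError(f"unknown cutoff_policy {cutoff_policy!r}")
    lk = linkage(condensed, method="average")
    labels = fcluster(lk, t=cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(g)
    # deterministic order: by first (TSS-sorted) member
    ordered = sorted(clusters.values(), key=lambda c: genes.index(c[0]))
    return GeneClusterSet(clusters=ordered, provenance="HiC", excluded=excluded)


def hic_cluster_all(
    contact_maps: dict[str, ContactMatrix],
    annotation: pd.DataFrame,
    cutoff_policy: str = "noise",
    cutoff_value: float | None = None,
) -> GeneClusterSet:
    """Spatial clustering over every chromosome, concatenated.

    Each returned cluster lives on a single chromosome; chromosomes are
    processed in sorted name order.
    """
    clusters: list[list[str]] = []
    excluded: list[str] = []
    for chrom in sorted(contact_maps):
        nm = pcc_matrix(diagonal_normalize(contact_maps[chrom]))
        cs = hic_cluster(nm, annotation, cutoff_policy, cutoff_value)
        clusters.extend(cs.clusters)
        excluded.extend(cs.excluded)
    return GeneClusterSet(clusters=clusters, provenance="HiC", excluded=excluded)
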