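"""Co-mutation ("DB") clustering of genes from somatic mutation tables.

A cohort of somatic point mutations is collapsed into a binary gene-by-sample
incidence matrix A (a_ij = 1 iff gene i is mutated at least once in sample j).
Genes are ranked by how many samples carry them mutated and clustered by a
greedy seeded pass over normalised Hamming similarity

    s_ij = 1 - h_ij / n_sp

where h_ij is the Hamming distance between the two binary sample profiles and
n_sp the number of samples.  The similarity threshold is selected from a grid
by maximising the significance of an unpaired two-sample t-test between the
Hi-C contact frequencies of intra-cluster and inter-cluster gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_THRESHOLD_GRID
from .errors import AnalysisError, DimensionError, FormatError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: mandatory columns of the MAF-like mutation TSV
MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


class MutationRecord(NamedTuple):
    """One somatic single-nucleotide substitution in one sample."""

    sample_id: str
    gene_id: str
    chrom: str
    position: int  # 1-based
    ref: str
    alt: str


@dataclass
class GeneSampleMatrix:
    """Binary genes x samples mutation incidence matrix.

    Rows are ordered by descending number of mutated samples (ties broken
    lexicographically by gene id); genes never observed mutated do not
    appear.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    @property
    def n_sp(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.matrix[self.gene_ids.index(gene_id)]


@dataclass
class GeneClusterSet:
    """Disjoint gene clusters with their provenance ("DB" or "HiC")."""

    clusters: list[list[str]]
    provenance: str
    threshold: float | None = None
    excluded: list[str] = field(default_factory=list)

    def labels(self) -> dict[str, int]:
        return {g: k for k, cl in enumerate(self.clusters) for g in cl}

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Parse a MAF-like TSV into validated :class:`MutationRecord` rows.

    Rows with a non-ACGT allele, ref == alt, or a non-positive position are
    dropped (the drop count is logged).  ``#`` comment lines are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table is missing column {col!r}")
    records: list[MutationRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        ref = str(getattr(row, "Reference_Allele")).upper()
        alt = str(getattr(row, "Tumor_Seq_Allele2")).upper()
        try:
            pos = int(getattr(row, "Start_Position"))
        except (TypeError, ValueError):
            dropped += 1
            continue
        if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt or pos < 1:
            dropped += 1
            continue
        records.append(
            MutationRecord(
                sample_id=str(getattr(row, "Tumor_Sample_Barcode")),
                gene_id=str(getattr(row, "Hugo_Symbol")),
                chrom=str(getattr(row, "Chromosome")),
                position=pos,
                ref=ref,
                alt=alt,
            )
        )
    if dropped:
        log.warning("dropped %d invalid mutation rows from %s", dropped, path)
    return records


def build_matrix(records: Sequence[MutationRecord]) -> GeneSampleMatrix:
    """Collapse mutation records into the binary gene x sample matrix.

    Multiplicity is ignored: a gene mutated several times in one sample
    still contributes a single 1.
    """
    if not records:
        raise AnalysisError("cannot build a gene-sample matrix from zero records")
    samples = sorted({r.sample_id for r in records})
    sample_idx = {s: j for j, s in enumerate(samples)}
    genes = sorted({r.gene_id for r in records})
    gene_idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    for r in records:
        mat[gene_idx[r.gene_id], sample_idx[r.sample_id]] = 1
    # rank genes by descending mutated-sample count, ties lexicographic
    counts = mat.sum(axis=1).astype(int)
    order = sorted(range(len(genes)), key=lambda i: (-counts[i], genes[i]))
    mat = mat[order]
    genes = [genes[i] for i in order]
    return GeneSampleMatrix(matrix=mat, gene_ids=genes, sample_ids=samples)


def hamming_similarity(gi: np.ndarray, gj: np.ndarray, n_sp: int | None = None) -> float:
    """Normalised Hamming similarity 1 - h/n_sp between two binary rows."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise DimensionError(f"row shapes differ: {gi.shape} vs {gj.shape}")
    if n_sp is None:
        n_sp = gi.size
    elif n_sp != gi.size:
        raise DimensionError(f"n_sp={n_sp} does not match row length {gi.size}")
    h = int(np.count_nonzero(gi != gj))
    return 1.0 - h / n_sp


def _similarity_matrix(mat: np.ndarray) -> np.ndarray:
    """All-pairs normalised Hamming similarity for a binary matrix."""
    a = mat.astype(np.int16)
    n_sp = a.shape[1]
    ones = a.sum(axis=1)
    both = a @ a.T
    # disagreements = |i| + |j| - 2*|i AND j|
    h = ones[:, None] + ones[None, :] - 2 * both
    return 1.0 - h / n_sp


def seed_cluster(m: GeneSampleMatrix, threshold: float) -> GeneClusterSet:
    """Greedy seeded clustering at a fixed similarity threshold.

    A single ordered pass: the top-ranked unclustered gene seeds a new
    cluster and absorbs every remaining unclustered gene whose similarity to
    the seed is >= threshold.  Every gene is assigned exactly once;
    singletons are allowed.
    """
    if not 0.0 < threshold <= 1.0:
        raise AnalysisError(f"threshold must be in (0, 1], got {threshold}")
    n = len(m.gene_ids)
    sim = _similarity_matrix(m.matrix)
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[str]] = []
    for i in range(n):
        if assigned[i]:
            continue
        members = [i]
        assigned[i] = True
        # strict tolerance guard: grid thresholds are exact decimals but the
        # similarity is a float ratio
        eligible = np.flatnonzero(~assigned & (sim[i] >= threshold - 1e-12))
        for j in eligible:
            members.append(int(j))
            assigned[j] = True
        clusters.append([m.gene_ids[k] for k in members])
    return GeneClusterSet(clusters=clusters, provenance="DB", threshold=threshold)


def comutated_pairs(m: GeneSampleMatrix) -> list[tuple[str, str]]:
    """Gene pairs observed mutated together in at least one sample."""
    a = m.matrix.astype(np.int32)
    co = a @ a.T
    ii, jj = np.nonzero(np.triu(co, k=1))
    return [(m.gene_ids[i], m.gene_ids[j]) for i, j in zip(ii, jj)]


def _pair_contact_table(
    gene_ids: Sequence[str],
    contact_maps: dict,
    annotation: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contact frequencies of all same-chromosome gene pairs.

    Returns (i_idx, j_idx, values) where the indices refer to positions in
    ``gene_ids``.  Genes missing from the annotation or from the contact
    maps, and pairs hitting masked bins, are omitted.
    """
    from .hic import gene_bins

    info = gene_bins(annotation, contact_maps)
    present = [(k, g) for k, g in enumerate(gene_ids) if g in info]
    ii_out, jj_out, vals = [], [], []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for k, g in present:
        chrom, b = info[g]
        by_chrom.setdefault(chrom, []).append((k, b))
    for chrom, entries in by_chrom.items():
        cm = contact_maps[chrom]
        idx = np.array([k for k, _ in entries])
        bins = np.array([b for _, b in entries])
        n = len(entries)
        iu, ju = np.triu_indices(n, k=1)
        bi, bj = bins[iu], bins[ju]
        ok = ~(cm.mask[bi] | cm.mask[bj])
        v = cm.matrix[bi[ok], bj[ok]]
        ii_out.append(idx[iu[ok]])
        jj_out.append(idx[ju[ok]])
        vals.append(v)
    if not vals:
        return np.array([], dtype=int), np.array([], dtype=int), np.array([])
    return np.concatenate(ii_out), np.concatenate(jj_out), np.concatenate(vals)


def safe_ttest_ind(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-sided t-test with the degenerate zero-variance cases
    resolved: identical constant populations give (0, 1); constant
    populations with different means give (+/-inf, 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def select_threshold(
    m: GeneSampleMatrix,
    contact_maps: dict,
    annotation: pd.DataFrame,
    grid: Iterable[float] = DEFAULT_THRESHOLD_GRID,
    welch: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Choose the Hamming threshold whose clustering best separates intra-
    from inter-cluster Hi-C contact frequencies.

    For every threshold on the grid the genes are clustered, same-chromosome
    gene pairs are split into intra-cluster and inter-cluster populations of
    contact frequencies, and a two-sided unpaired t-test is run.  The
    threshold with the smallest p-value wins; exact ties go to the larger
    threshold (tighter clusters).  Thresholds where either population has
    fewer than two pairs are skipped.

    Returns the winning threshold and the full per-threshold grid
    (threshold, t, p, n_intra, n_inter, mean_intra, mean_inter).
    """
    grid = sorted(grid)
    ii, jj, vals = _pair_contact_table(m.gene_ids, contact_maps, annotation)
    rows = []
    best: tuple[float, float] | None = None  # (p, threshold)
    for thr in grid:
        cs = seed_cluster(m, thr)
        lab = cs.labels()
        gl = np.array([lab[g] for g in m.gene_ids])
        if len(vals) == 0:
            continue
        intra_mask = gl[ii] == gl[jj]
        intra = vals[intra_mask]
        inter = vals[~intra_mask]
        if intra.size < 2 or inter.size < 2:
            rows.append((thr, np.nan, np.nan, intra.size, inter.size, np.nan, np.nan))
            continue
        t, p = safe_ttest_ind(intra, inter, welch)
        rows.append(
            (thr, float(t), float(p), intra.size, inter.size,
             float(intra.mean()), float(inter.mean()))
        )
        if np.isfinite(p) and (best is None or p <= best[0]):
            best = (float(p), thr)
    table = pd.DataFrame(
        rows,
        columns=["threshold", "t", "p", "n_intra", "n_inter", "mean_intra", "mean_inter"],
    )
    if best is None:
        raise AnalysisError(
            "no threshold produced both intra- and inter-cluster contact pairs"
        )
    return best[1], table
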