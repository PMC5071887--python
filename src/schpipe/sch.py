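"""Spatial co-mutation hotspot (SCH) detection.

An SCH is the intersection (>= 2 genes) of one co-mutation ("DB") gene
cluster with one spatial ("Hi-C") gene cluster; every SCH therefore lives
on a single chromosome and each of its gene pairs is simultaneously
co-mutation-clustered and spatially clustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comut import GeneClusterSet, _pair_contact_table, safe_ttest_ind
from .errors import AnalysisError
from .hic import ContactMatrix

__all__ = [
    "SCH",
    "detect_schs",
    "intra_inter_comparison",
    "IntraInterReport",
    "pair_f1",
    "gene_pairs",
]


@dataclass
class SCH:
    sch_id: str
    gene_ids: list[str]
    chrom: str
    source_db_cluster: int
    source_hic_cluster: int


def detect_schs(
    db: GeneClusterSet,
    hic: GeneClusterSet,
    annotation: pd.DataFrame | None = None,
) -> list[SCH]:
    """Overlap DB clusters with Hi-C clusters into SCHs.

    One SCH per (db cluster, hic cluster) pair whose intersection has at
    least two genes.  A DB cluster spanning chromosomes may spawn several
    SCHs through different per-chromosome Hi-C clusters.  Ids are assigned
    in (db index, hic index) order.
    """
    chrom_of: dict[str, str] = {}
    if annotation is not None:
        chrom_of = dict(zip(annotation["gene_id"], annotation["chrom"]))
    schs: list[SCH] = []
    hic_sets = [set(c) for c in hic.clusters]
    for i, dbc in enumerate(db.clusters):
        dbs = set(dbc)
        for j, hs in enumerate(hic_sets):
            inter = dbs & hs
            if len(inter) >= 2:
                genes = sorted(inter)
                chroms = {chrom_of.get(g, "?") for g in genes}
                chrom = chroms.pop() if len(chroms) == 1 else "?"
                schs.append(
                    SCH(
                        sch_id=f"SCH{len(schs) + 1:04d}",
                        gene_ids=genes,
                        chrom=chrom,
                        source_db_cluster=i,
                        source_hic_cluster=j,
                    )
                )
    return schs


@dataclass
class IntraInterReport:
    """Intra- vs inter-class contact comparison (unpaired two-sided t)."""

    intra: np.ndarray
    inter: np.ndarray
    p: float
    t: float
    alpha: float

    @property
    def mean_intra(self) -> float:
        return float(self.intra.mean())

    @property
    def mean_inter(self) -> float:
        return float(self.inter.mean())

    @property
    def passed(self) -> bool:
        return bool(self.p < self.alpha and self.mean_intra > self.mean_inter)


def intra_inter_comparison(
    clusters: GeneClusterSet,
    contact_maps: dict[str, ContactMatrix],
    annotation: pd.DataFrame,
    alpha: float = 0.005,
    welch: bool = False,
) -> IntraInterReport:
    """Compare contact frequencies of intra- vs inter-cluster gene pairs.

    Only same-chromosome pairs on unmasked bins enter; the pass flag
    requires both p < alpha and a higher intra-class mean.
    """
    genes = [g for c in clusters.clusters for g in c]
    lab = clusters.labels()
    ii, jj, vals = _pair_contact_table(genes, contact_maps, annotation)
    if vals.size == 0:
        raise AnalysisError("no same-chromosome gene pairs with contact data")
    gl = np.array([lab[g] for g in genes])
    intra_mask = gl[ii] == gl[jj]
    intra = vals[intra_mask]
    inter = vals[~intra_mask]
    if intra.size < 2 or inter.size < 2:
        raise AnalysisError(
            f"need >= 2 pairs per class, got intra={intra.size} inter={inter.size}"
        )
    t, p = safe_ttest_ind(intra, inter, welch)
    return IntraInterReport(intra=intra, inter=inter, p=float(p), t=float(t), alpha=alpha)


def gene_pairs(groups: Iterable[Sequence[str]]) -> set[frozenset[str]]:
    """Unordered within-group gene pairs of a collection of gene groups."""
    pairs: set[frozenset[str]] = set()
    for g in groups:
        for a, b in combinations(sorted(set(g)), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def pair_f1(
    predicted_groups: Iterable[Sequence[str]],
    truth_groups: Iterable[Sequence[str]],
) -> float:
    """Gene-pair-level F1 of predicted gene groups against planted truth.

    Both sides are reduced to their sets of within-group unordered pairs.
    Returns 0 when either side has no pairs (and they differ); 1 when both
    are empty.
    """
    pred = gene_pairs(predicted_groups)
    truth = gene_pairs(truth_groups)
    if not pred and not truth:
        return 1.0
    if not pred or not truth:
        return 0.0
    tp = len(pred & truth)
    precision = tp / len(pred)
    recall = tp / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
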