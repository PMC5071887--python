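"""12-type mutational-signature similarity and complementing-score analysis.

A point substitution is classified by its ordered ref>alt pair on the +
strand, giving 12 types (no pyrimidine collapsing).  Per gene the type
counts form the rows of the gene x 12 matrix M; thresholding at >= 1 gives
the binary matrix M' used for Jaccard distances.  The complementing score
of a count vector measures how far its mass is from being balanced across
the six direction-reversed substitution pairs (e.g. A>T with T>A):

    score = 1 - 2 * sum_pairs min(n_xy, n_yx) / N

so 0 means perfectly complementary counts and 1 means no complementary
pairing at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .comut import MutationRecord
from .errors import AnalysisError

#: the 12 ordered substitution types, lexicographic over (ref, alt)
TYPE_ORDER: tuple[str, ...] = tuple(
    f"{r}>{a}" for r, a in sorted(permutations("ACGT", 2))
)
_TYPE_INDEX = {t: i for i, t in enumerate(TYPE_ORDER)}

#: index of the direction-reversed partner of each type
COMPLEMENT_INDEX = tuple(
    _TYPE_INDEX[f"{t[2]}>{t[0]}"] for t in TYPE_ORDER
)


def mutation_type_of(ref: str, alt: str) -> int:
    """Index (0..11) of the substitution ref>alt in :data:`TYPE_ORDER`."""
    key = f"{ref}>{alt}"
    if ref == alt or key not in _TYPE_INDEX:
        raise AnalysisError(f"invalid substitution {ref!r}>{alt!r}")
    return _TYPE_INDEX[key]


@dataclass
class MutationTypeMatrix:
    """Gene x 12 substitution-type count matrix M and its binary form M'."""

    counts: np.ndarray
    gene_ids: list[str]

    @property
    def binary(self) -> np.ndarray:
        return (self.counts >= 1).astype(np.uint8)

    def counts_for(self, genes: Iterable[str]) -> np.ndarray:
        """Pooled 12-vector of type counts over a gene group."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes if g in idx]
        if not rows:
            return np.zeros(12, dtype=self.counts.dtype)
        return self.counts[rows].sum(axis=0)

    def row(self, gene: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene)]


def build_type_matrix(
    records: Sequence[MutationRecord], gene_ids: Sequence[str] | None = None
) -> MutationTypeMatrix:
    """Tabulate per-gene substitution-type counts from mutation records."""
    if gene_ids is None:
        gene_ids = sorted({r.gene_id for r in records})
    idx = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(gene_ids), 12), dtype=np.int64)
    for r in records:
        i = idx.get(r.gene_id)
        if i is not None:
            counts[i, mutation_type_of(r.ref, r.alt)] += 1
    return MutationTypeMatrix(counts=counts, gene_ids=list(gene_ids))


def jaccard_distance(gi: np.ndarray, gj: np.ndarray) -> float:
    """1 - |intersection| / |union| of the active types of two binary rows."""
    gi = np.asarray(gi).astype(bool)
    gj = np.asarray(gj).astype(bool)
    union = int(np.count_nonzero(gi | gj))
    if union == 0:
        raise AnalysisError("Jaccard distance undefined for two all-zero vectors")
    inter = int(np.count_nonzero(gi & gj))
    return 1.0 - inter / union


def _pairwise_jaccard(binary: np.ndarray, rows: Sequence[int]) -> list[float]:
    out = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            gi, gj = binary[rows[a]], binary[rows[b]]
            if (gi | gj).any():
                out.append(jaccard_distance(gi, gj))
    return out


def _group_mean_jaccards(
    groups: Sequence[Sequence[str]], mtm: MutationTypeMatrix
) -> list[float]:
    """Mean pairwise Jaccard distance of each gene group (>=1 valid pair)."""
    idx = {g: i for i, g in enumerate(mtm.gene_ids)}
    binary = mtm.binary
    means = []
    for group in groups:
        rows = [idx[g] for g in group if g in idx]
        dists = _pairwise_jaccard(binary, rows)
        if dists:
            means.append(float(np.mean(dists)))
    return means


@dataclass
class JaccardReport:
    """Signature-dissimilarity distributions and their tests vs intra-SCH."""

    intra_sch: list[float]
    intra_db: list[float]
    intra_hic: list[float]
    inter_sch: list[float]
    p_vs_db: float
    p_vs_hic: float
    p_vs_inter: float

    def means(self) -> dict[str, float]:
        return {
            name: (float(np.mean(v)) if v else float("nan"))
            for name, v in [
                ("intra_sch", self.intra_sch),
                ("intra_db", self.intra_db),
                ("intra_hic", self.intra_hic),
                ("inter_sch", self.inter_sch),
            ]
        }


def group_jaccard_report(
    schs: Sequence,
    db_clusters: Sequence[Sequence[str]],
    hic_clusters: Sequence[Sequence[str]],
    mtm: MutationTypeMatrix,
) -> JaccardReport:
    """Compare intra-SCH signature dissimilarity with DB, Hi-C, and inter-SCH.

    Intra distributions hold one mean pairwise Jaccard distance per cluster;
    the inter-SCH distribution holds the pairwise distances of gene pairs
    spanning two different SCHs.  Each other distribution is tested against
    intra-SCH by a two-sided unpaired t-test.
    """
    sch_groups = [list(s.gene_ids) for s in schs]
    intra_sch = _group_mean_jaccards(sch_groups, mtm)
    intra_db = _group_mean_jaccards([c for c in db_clusters if len(c) >= 2], mtm)
    intra_hic = _group_mean_jaccards([c for c in hic_clusters if len(c) >= 2], mtm)
    idx = {g: i for i, g in enumerate(mtm.gene_ids)}
    binary = mtm.binary
    inter_sch: list[float] = []
    for a in range(len(sch_groups)):
        for b in range(a + 1, len(sch_groups)):
            for g1 in sch_groups[a]:
                for g2 in sch_groups[b]:
                    if g1 in idx and g2 in idx and g1 != g2:
                        gi, gj = binary[idx[g1]], binary[idx[g2]]
                        if (gi | gj).any():
                            inter_sch.append(jaccard_distance(gi, gj))

    def _test(other: list[float]) -> float:
        if len(intra_sch) < 2 or len(other) < 2:
            return float("nan")
        return float(stats.ttest_ind(intra_sch, other).pvalue)

    return JaccardReport(
        intra_sch=intra_sch,
        intra_db=intra_db,
        intra_hic=intra_hic,
        inter_sch=inter_sch,
        p_vs_db=_test(intra_db),
        p_vs_hic=_test(intra_hic),
        p_vs_inter=_test(inter_sch),
    )


def complementing_score(counts: np.ndarray | Mapping[str, int]) -> float:
    """Complementing-mutation score of a 12-vector of type counts.

    Accepts either a 12-vector ordered as :data:`TYPE_ORDER` or a mapping
    like ``{"A>T": 2, "T>A": 2}``.  Undefined (raises) for an all-zero
    vector.
    """
    if isinstance(counts, Mapping):
        vec = np.zeros(12)
        for key, v in counts.items():
            vec[_TYPE_INDEX[key]] = v
    else:
        vec = np.asarray(counts, dtype=float)
        if vec.shape != (12,):
            raise AnalysisError("count vector must have length 12")
    if (vec < 0).any():
        raise AnalysisError("negative type count")
    total = vec.sum()
    if total == 0:
        raise AnalysisError("complementing score undefined for zero mutations")
    paired = 0.0
    for i in range(12):
        j = COMPLEMENT_INDEX[i]
        if i < j:
            paired += min(vec[i], vec[j])
    return float(1.0 - 2.0 * paired / total)


@dataclass
class ComplementReport:
    sch_scores: dict[str, float]
    background_score: float
    z: float
    p: float


def complementary_z_test(schs: Sequence, mtm: MutationTypeMatrix) -> ComplementReport:
    """Z-test of per-SCH complementing scores against the pooled background.

    The background score pools the type counts of every SCH gene into one
    combined cluster.  Z = (mean score - background) / (sd / sqrt(k)) over
    the k SCHs with a defined score; the p-value is two-sided normal.
    """
    scores: dict[str, float] = {}
    for s in schs:
        pooled = mtm.counts_for(s.gene_ids)
        if pooled.sum() > 0:
            scores[s.sch_id] = complementing_score(pooled)
    if len(scores) < 2:
        raise AnalysisError("complementary Z-test needs >= 2 SCHs with mutations")
    all_genes = sorted({g for s in schs for g in s.gene_ids})
    background = complementing_score(mtm.counts_for(all_genes))
    vals = np.array(list(scores.values()))
    sd = vals.std(ddof=1)
    if sd == 0:
        z = 0.0 if np.isclose(vals.mean(), background) else float("inf")
        p = 1.0 if z == 0.0 else 0.0
    else:
        z = float((vals.mean() - background) / (sd / np.sqrt(len(vals))))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComplementReport(sch_scores=scores, background_score=background, z=z, p=p)
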