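"""Pathway enrichment and driver-gene content of gene cluster sets.

A cluster's enrichment p-value is the minimum, over all pathway gene sets,
of the upper-tail hypergeometric probability of its overlap with the
pathway; no multiple-testing correction is applied (the minimum itself is
the reported statistic, with its selection bias acknowledged).  The
universe N is the full gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .errors import AnalysisError, FormatError


@dataclass
class PathwayDB:
    """Named pathway gene sets over a fixed gene universe."""

    pathways: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.pathways = {k: set(v) & self.universe for k, v in self.pathways.items()}

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    def fractions(self) -> dict[str, float]:
        """Per-pathway fraction p of the universe assigned to the pathway."""
        n = self.n_universe
        return {k: len(v) / n for k, v in self.pathways.items()}


def read_gmt(path: str | Path, universe: Iterable[str]) -> PathwayDB:
    """Read tab-separated GMT (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            pathways[parts[0]] = set(parts[2:])
    return PathwayDB(pathways=pathways, universe=set(universe))


def write_gmt(db: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(db):
            genes = "\t".join(sorted(db[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_driver_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def hypergeom_tail(N: int, K: int, n: int, r: int) -> float:
    """Upper-tail P(X >= r) for overlap r of an n-gene cluster with a
    K-gene pathway in an N-gene universe."""
    if not (0 <= r <= min(n, K) <= N) or n > N or K > N:
        raise AnalysisError(f"inconsistent hypergeometric parameters N={N} K={K} n={n} r={r}")
    if r == 0:
        return 1.0
    return float(stats.hypergeom.sf(r - 1, N, K, n))


def cluster_enrichment(
    cluster: Iterable[str], db: PathwayDB
) -> tuple[str, float, pd.DataFrame]:
    """Best pathway, cluster p-value (min over pathways), per-pathway table.

    The table is sorted ascending by p (ties by pathway id); genes outside
    the universe are ignored.
    """
    if not db.pathways:
        raise AnalysisError("empty pathway database")
    genes = set(cluster) & db.universe
    if not genes:
        raise AnalysisError("cluster has no genes in the universe")
    N = db.n_universe
    n = len(genes)
    rows = []
    for name in sorted(db.pathways):
        pset = db.pathways[name]
        r = len(genes & pset)
        p = hypergeom_tail(N, len(pset), n, r)
        rows.append((name, len(pset), r, p))
    table = pd.DataFrame(rows, columns=["pathway", "K", "overlap", "p"])
    table = table.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    best = table.iloc[0]
    return str(best["pathway"]), float(best["p"]), table


def enrichment_fraction(
    cluster_sets: Mapping[str, Sequence[Sequence[str]]],
    db: PathwayDB,
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Fraction of clusters with enrichment p < cutoff, per dataset x cutoff."""
    if not cutoffs:
        raise AnalysisError("empty cutoff list")
    rows = []
    for name, clusters in cluster_sets.items():
        ps = []
        for cl in clusters:
            if set(cl) & db.universe:
                ps.append(cluster_enrichment(cl, db)[1])
        ps_arr = np.asarray(ps)
        for cut in cutoffs:
            frac = float((ps_arr < cut).mean()) if ps_arr.size else float("nan")
            rows.append((name, float(cut), frac, int(ps_arr.size)))
    return pd.DataFrame(rows, columns=["dataset", "cutoff", "fraction", "n_clusters"])


def pathway_coverage(
    cluster_sets: Mapping[str, Sequence[Sequence[str]]],
    db: PathwayDB,
    cutoff: float,
) -> dict[str, int]:
    """Distinct significantly enriched (argmin) pathways per dataset."""
    out: dict[str, int] = {}
    for name, clusters in cluster_sets.items():
        hit: set[str] = set()
        for cl in clusters:
            if not set(cl) & db.universe:
                continue
            best, p, _ = cluster_enrichment(cl, db)
            if p < cutoff:
                hit.add(best)
        out[name] = len(hit)
    return out


@dataclass
class DriverReport:
    percentages: dict[str, float]
    counts: dict[str, tuple[int, int]]  # dataset -> (drivers, genes)
    p_sch_vs_db: float
    p_sch_vs_hic: float


def driver_fraction(
    cluster_sets: Mapping[str, Sequence[Sequence[str]]],
    drivers: Iterable[str],
) -> DriverReport:
    """Percent of dataset genes in the driver list, with two-proportion
    z-tests of SCH against DB and against HiC (when those datasets exist).
    """
    drivers = set(drivers)
    if not drivers:
        raise AnalysisError("empty driver list")
    counts: dict[str, tuple[int, int]] = {}
    perc: dict[str, float] = {}
    for name, clusters in cluster_sets.items():
        genes = {g for cl in clusters for g in cl}
        if not genes:
            continue
        k = len(genes & drivers)
        counts[name] = (k, len(genes))
        perc[name] = 100.0 * k / len(genes)

    def _ztest(a: str, b: str) -> float:
        if a not in counts or b not in counts:
            return float("nan")
        (k1, n1), (k2, n2) = counts[a], counts[b]
        if k1 == k2 == 0 or (k1 == n1 and k2 == n2):
            return 1.0
        _, p = proportions_ztest([k1, k2], [n1, n2])
        return float(p)

    return DriverReport(
        percentages=perc,
        counts=counts,
        p_sch_vs_db=_ztest("SCH", "DB"),
        p_sch_vs_hic=_ztest("SCH", "HiC"),
    )
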