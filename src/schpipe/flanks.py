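"""Conservation of the 21-nt sequences flanking mutation points.

Every usable mutation yields a window of 10 reference nucleotides on each
side of the mutated base (window length 21, mutation at 1-based index 11).
Windows of a gene group are aligned positionally — they are anchored on the
mutation, so no gapped alignment is needed — and scored by the mean Shannon
entropy (base 2) of the 21 columns: 0 bits means perfectly conserved, 2 bits
is the i.i.d.-uniform limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .comut import MutationRecord
from .errors import AnalysisError, ConfigError
from .signatures import mutation_type_of

log = logging.getLogger(__name__)

WINDOW_FLANK = 10
WINDOW_LEN = 2 * WINDOW_FLANK + 1
MUT_INDEX = WINDOW_FLANK  # 0-based center; 1-based index 11

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class FlankWindow(NamedTuple):
    gene_id: str
    chrom: str
    position: int  # 1-based mutation point
    sequence: str  # 21 uppercase nucleotides, reference at the center
    mut_type: int  # 0..11 substitution-type index


def _contig_seq(reference: Mapping[str, object], chrom: str) -> object:
    try:
        return reference[chrom]
    except KeyError as exc:
        raise AnalysisError(f"contig {chrom!r} missing from reference") from exc


def extract_flanks(
    records: Sequence[MutationRecord], reference: Mapping[str, object]
) -> list[FlankWindow]:
    """Extract the 21-nt + strand reference window around every mutation.

    ``reference`` maps contig name to anything sliceable with 0-based
    coordinates (a dict of strings, a ``pyfaidx.Fasta``, ...).  Windows that
    overhang a contig end, contain non-ACGT characters, or whose center
    base disagrees with the record's reference allele are dropped; the drop
    count is logged.
    """
    windows: list[FlankWindow] = []
    dropped_bounds = dropped_n = dropped_ref = 0
    for r in records:
        seq_obj = _contig_seq(reference, r.chrom)
        start = r.position - 1 - WINDOW_FLANK  # 0-based inclusive
        if start < 0:
            dropped_bounds += 1
            continue
        raw = seq_obj[start : start + WINDOW_LEN]
        seq = str(raw).upper()
        if len(seq) < WINDOW_LEN:
            dropped_bounds += 1
            continue
        if any(b not in _BASE_CODE for b in seq):
            dropped_n += 1
            continue
        if seq[MUT_INDEX] != r.ref:
            dropped_ref += 1
            continue
        windows.append(
            FlankWindow(
                gene_id=r.gene_id,
                chrom=r.chrom,
                position=r.position,
                sequence=seq,
                mut_type=mutation_type_of(r.ref, r.alt),
            )
        )
    if dropped_bounds or dropped_n or dropped_ref:
        log.warning(
            "extract_flanks dropped %d boundary, %d ambiguous, %d ref-mismatch windows",
            dropped_bounds, dropped_n, dropped_ref,
        )
    return windows


def _encode(windows: Sequence[FlankWindow | str]) -> np.ndarray:
    seqs = [w.sequence if isinstance(w, FlankWindow) else w for w in windows]
    return np.array([[_BASE_CODE[b] for b in s] for s in seqs], dtype=np.int8)


def position_frequency_matrix(windows: Sequence[FlankWindow | str]) -> np.ndarray:
    """4 x 21 nucleotide frequency matrix (rows A, C, G, T)."""
    enc = _encode(windows)
    pfm = np.zeros((4, WINDOW_LEN))
    for col in range(WINDOW_LEN):
        pfm[:, col] = np.bincount(enc[:, col], minlength=4)
    return pfm / len(windows)


def conservation_score(
    windows: Sequence[FlankWindow | str], exclude_center: bool = False
) -> float:
    """Mean per-column Shannon entropy (bits) of aligned flank windows.

    Lower is more conserved; identical windows score 0.  Raw column
    frequencies are used (no pseudocounts).  ``exclude_center`` drops the
    mutation position itself from the average.
    """
    if len(windows) < 2:
        raise AnalysisError("conservation score needs >= 2 windows")
    pfm = position_frequency_matrix(windows)
    cols = [c for c in range(WINDOW_LEN) if not (exclude_center and c == MUT_INDEX)]
    ent = 0.0
    for c in cols:
        p = pfm[:, c]
        p = p[p > 0]
        ent += float(-(p * np.log2(p)).sum())
    return ent / len(cols)


@dataclass
class ConservationReport:
    sch_scores: dict[str, float]
    sch_sizes: dict[str, int]
    background_mean: float
    background_sd: float
    z: float
    p: float
    n_resamples: int


def conservation_background_test(
    sch_windows: Mapping[str, Sequence[FlankWindow]],
    pooled_windows: Sequence[FlankWindow],
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> ConservationReport:
    """Z-test of per-SCH conservation against size-matched random groups.

    For every SCH with >= 2 windows, ``n_resamples`` random groups of the
    same size are drawn (with replacement across groups, without within a
    group) from the pooled window set.  Because the entropy score of a
    window group depends strongly on its size, each SCH is standardized
    against its own size-matched background (z_i = (s_i - mu_i) / sd_i)
    and the per-SCH z-scores are combined as Z = sum(z_i) / sqrt(k)
    (Stouffer).  Negative Z means the SCHs are more conserved than
    size-matched random groups; the reported background mean/sd pool all
    resampled scores for reference.
    """
    if n_resamples < 100:
        log.warning("conservation background: n_resamples=%d < 100 is unreliable", n_resamples)
    if n_resamples < 1:
        raise ConfigError("n_resamples must be >= 1")
    rng = rng or np.random.default_rng()
    usable = {k: v for k, v in sch_windows.items() if len(v) >= 2}
    if len(usable) < 2:
        raise AnalysisError("conservation test needs >= 2 SCHs with >= 2 windows")
    pool = list(pooled_windows)
    if len(pool) < 2:
        raise AnalysisError("pooled window set too small")
    scores = {k: conservation_score(v) for k, v in usable.items()}
    all_bg = []
    per_sch_z = []
    for k in sorted(usable):
        size = min(len(usable[k]), len(pool))
        bg_k = []
        for _ in range(n_resamples):
            idx = rng.choice(len(pool), size=size, replace=False)
            bg_k.append(conservation_score([pool[i] for i in idx]))
        bg_k = np.asarray(bg_k)
        all_bg.append(bg_k)
        sd_k = bg_k.std(ddof=1)
        if sd_k == 0:
            z_k = 0.0 if np.isclose(scores[k], bg_k.mean()) else np.sign(
                scores[k] - bg_k.mean()
            ) * float("inf")
        else:
            z_k = (scores[k] - bg_k.mean()) / sd_k
        per_sch_z.append(z_k)
    bg = np.concatenate(all_bg)
    mu, sd = float(bg.mean()), float(bg.std(ddof=1))
    per_sch_z = np.asarray(per_sch_z)
    finite = per_sch_z[np.isfinite(per_sch_z)]
    if len(finite) < len(per_sch_z):
        z = float(np.sign(per_sch_z[~np.isfinite(per_sch_z)].sum()) * np.inf)
        p = 0.0
    else:
        z = float(per_sch_z.sum() / np.sqrt(len(per_sch_z)))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ConservationReport(
        sch_scores=scores,
        sch_sizes={k: len(v) for k, v in usable.items()},
        background_mean=mu,
        background_sd=sd,
        z=z,
        p=p,
        n_resamples=n_resamples,
    )


@dataclass
class SimilarityConservationReport:
    """Pairwise conservation split by mutation-type concordance (0 = same)."""

    same_type_scores: list[float]
    diff_type_scores: list[float]
    p: float
    evaluable: bool

    def means(self) -> tuple[float, float]:
        m0 = float(np.mean(self.same_type_scores)) if self.same_type_scores else float("nan")
        m1 = float(np.mean(self.diff_type_scores)) if self.diff_type_scores else float("nan")
        return m0, m1


def signature_conservation_correlation(
    sch_windows: Mapping[str, Sequence[FlankWindow]],
    max_pairs_per_sch: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimilarityConservationReport:
    """Within-SCH window pairs: does same mutation type imply conservation?

    Every within-SCH pair of windows is labelled 0 (identical substitution
    type) or 1 (distinct) and scored with the 2-sequence conservation
    entropy; the two classes are compared by an unpaired two-sided t-test.
    """
    same: list[float] = []
    diff: list[float] = []
    for k in sorted(sch_windows):
        ws = list(sch_windows[k])
        pairs = [(a, b) for a in range(len(ws)) for b in range(a + 1, len(ws))]
        if max_pairs_per_sch is not None and len(pairs) > max_pairs_per_sch:
            rng = rng or np.random.default_rng()
            sel = rng.choice(len(pairs), size=max_pairs_per_sch, replace=False)
            pairs = [pairs[i] for i in sel]
        for a, b in pairs:
            score = conservation_score([ws[a], ws[b]])
            if ws[a].mut_type == ws[b].mut_type:
                same.append(score)
            else:
                diff.append(score)
    if len(same) < 2 or len(diff) < 2:
        return SimilarityConservationReport(same, diff, float("nan"), evaluable=False)
    p = float(stats.ttest_ind(same, diff).pvalue)
    return SimilarityConservationReport(same, diff, p, evaluable=True)
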