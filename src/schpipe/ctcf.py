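"""Aggregate signal (e.g. CTCF ChIP-seq) profiles around gene TSSs.

The track is piecewise-constant (bedGraph); gaps count as signal 0.  A TSS
metaprofile averages coverage-weighted mean signal in fixed-width bins over
a +/- window around each TSS, with minus-strand genes mirrored, and the
SCH-vs-background comparison tests per-TSS mean signal with an unpaired
two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, FormatError


@dataclass
class SignalTrack:
    """Sorted non-overlapping intervals per chromosome.

    ``data[chrom] = (starts, ends, values)`` with 0-based half-open
    coordinates.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.data.items()}
        )


def _canonicalize(
    raw: dict[str, list[tuple[int, int, float]]]
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ivals in raw.items():
        ivals.sort()
        starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
        vals = np.array([v for _, _, v in ivals], dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"overlapping intervals on {chrom}")
        if np.any(ends <= starts):
            raise FormatError(f"empty or inverted interval on {chrom}")
        if not np.all(np.isfinite(vals)):
            raise FormatError(f"non-finite signal value on {chrom}")
        out[chrom] = (starts, ends, vals)
    return out


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a bedGraph file into a canonical (sorted, checked) track."""
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"bad bedGraph line: {line[:60]!r}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            raw.setdefault(chrom, []).append((start, end, value))
    return SignalTrack(data=_canonicalize(raw))


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, vals = track.data[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def _integral_at(
    starts: np.ndarray, ends: np.ndarray, vals: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Integral of the piecewise-constant track over [0, x) (gaps = 0)."""
    areas = vals * (ends - starts)
    cum = np.concatenate([[0.0], np.cumsum(areas)])
    j = np.searchsorted(starts, x, side="right") - 1
    out = np.where(j >= 0, cum[np.maximum(j, 0)], 0.0)
    jj = np.maximum(j, 0)
    partial = vals[jj] * np.clip(x - starts[jj], 0, ends[jj] - starts[jj])
    return out + np.where(j >= 0, partial, 0.0)


@dataclass
class TSSProfile:
    """Mean metaprofile plus the per-TSS window means used for testing."""

    offsets: np.ndarray  # bin start offsets relative to TSS
    profile: np.ndarray  # mean signal per bin over all TSSs
    per_tss_mean: np.ndarray
    n_clipped: int


def tss_profile(
    track: SignalTrack,
    tss_list: Sequence[tuple[str, int, str]],
    window: int = 5000,
    bin_width: int = 50,
) -> TSSProfile:
    """Strand-oriented mean signal profile around a list of TSSs.

    ``tss_list`` holds (chrom, 1-based TSS, strand).  Each of the
    2*window/bin_width bins carries the coverage-weighted mean of the
    piecewise-constant signal; minus-strand profiles are reversed before
    averaging.  Windows clipped at a contig start are kept (missing bases
    count 0) and counted in ``n_clipped``.
    """
    if not tss_list:
        raise AnalysisError("empty TSS list")
    if window % bin_width:
        raise AnalysisError("window must be a multiple of bin_width")
    nb = 2 * window // bin_width
    profiles = np.zeros((len(tss_list), nb))
    means = np.zeros(len(tss_list))
    n_clipped = 0
    for k, (chrom, tss, strand) in enumerate(tss_list):
        center = int(tss) - 1  # 0-based
        edges = center - window + bin_width * np.arange(nb + 1)
        if edges[0] < 0:
            n_clipped += 1
        if chrom in track.data:
            starts, ends, vals = track.data[chrom]
            F = _integral_at(starts, ends, vals, np.clip(edges, 0, None).astype(float))
            binned = np.diff(F) / bin_width
        else:
            binned = np.zeros(nb)
        if strand == "-":
            binned = binned[::-1]
        profiles[k] = binned
        means[k] = binned.mean()
    offsets = -window + bin_width * np.arange(nb)
    return TSSProfile(
        offsets=offsets,
        profile=profiles.mean(axis=0),
        per_tss_mean=means,
        n_clipped=n_clipped,
    )


@dataclass
class CTCFReport:
    sch_means: np.ndarray
    background_means: np.ndarray
    p: float
    t: float
    qq_sch: np.ndarray
    qq_background: np.ndarray

    @property
    def mean_sch(self) -> float:
        return float(self.sch_means.mean())

    @property
    def mean_background(self) -> float:
        return float(self.background_means.mean())


def compare_tss_signal(
    track: SignalTrack,
    sch_tss: Sequence[tuple[str, int, str]],
    background_tss: Sequence[tuple[str, int, str]],
    window: int = 5000,
    bin_width: int = 50,
) -> CTCFReport:
    """Unpaired t-test of per-TSS mean signal, SCH genes vs background.

    Also returns matched quantile vectors (101 probabilities) for a Q-Q
    plot of the two distributions.
    """
    if len(sch_tss) < 2 or len(background_tss) < 2:
        raise AnalysisError("need >= 2 TSSs in each group")
    sch = tss_profile(track, sch_tss, window, bin_width).per_tss_mean
    bkg = tss_profile(track, background_tss, window, bin_width).per_tss_mean
    if sch.std() == 0 and bkg.std() == 0:
        t = 0.0
        p = 1.0 if np.isclose(sch.mean(), bkg.mean()) else 0.0
    else:
        t, p = stats.ttest_ind(sch, bkg)
    probs = np.linspace(0, 1, 101)
    return CTCFReport(
        sch_means=sch,
        background_means=bkg,
        p=float(p),
        t=float(t),
        qq_sch=np.quantile(sch, probs),
        qq_background=np.quantile(bkg, probs),
    )
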