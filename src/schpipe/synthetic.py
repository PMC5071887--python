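"""Synthetic cohort + Hi-C generator with planted ground truth.

Generates every pipeline input from one :class:`SyntheticConfig`:

* a gene annotation whose planted hotspot genes occupy contiguous 40 kb-bin
  blocks, one gene per bin, with all remaining genes scattered uniformly
  over the unplanted bins;
* per-chromosome contact matrices with Poisson counts around a power-law
  distance decay, block entries boosted by ``contact_boost``;
* a mutation cohort in which each planted hotspot fires per sample with
  probability ``comut_prob`` (mutating every hotspot gene once) while
  background genes mutate independently;
* a reference sequence carrying each hotspot's 21-nt flank motif at the
  (per-gene fixed) mutation sites, a CTCF-like bedGraph boosted around
  planted TSSs, pathway gene sets embedding a fraction of hotspots, and a
  driver list biased toward planted genes.

Each planted hotspot is assigned one of the 12 substitution types by
cycling a fixed ordering in which consecutive hotspots receive
direction-reversed (complementary) types, so that the pooled background of
several hotspots is more complementary than any single hotspot — the
structure the complementing-score analysis is designed to detect.

All randomness flows from ``cfg.seed`` through named child streams, so a
fixed config reproduces every output byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .comut import MAF_COLUMNS, MutationRecord
from .config import SyntheticConfig
from .ctcf import SignalTrack, write_bedgraph
from .errors import ConfigError
from .hic import ContactMatrix, write_contact_matrix
from .signatures import TYPE_ORDER

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}

#: substitution-type indices ordered so consecutive entries are
#: direction-reversed partners (A>T, T>A, C>G, G>C, ...)
_COMPLEMENT_CYCLE = tuple(
    TYPE_ORDER.index(t)
    for pair in (("A>T", "T>A"), ("C>G", "G>C"), ("A>C", "C>A"),
                 ("A>G", "G>A"), ("C>T", "T>C"), ("G>T", "T>G"))
    for t in pair
)

#: margin kept between a TSS (or mutation site) and bin/contig boundaries
_EDGE_MARGIN = 100


@dataclass
class Hotspot:
    hotspot_id: str
    chrom: str
    genes: list[str]
    bin_lo: int
    bin_hi: int  # inclusive
    mut_type: int  # 0..11 index into TYPE_ORDER
    motif: str  # 21-nt flank motif, center = the type's reference base


@dataclass
class PlantedTruth:
    """Planted structure: hotspot membership, per-gene TSS/bin/mutation site."""

    hotspots: list[Hotspot]
    gene_tss: dict[str, tuple[str, int]]  # gene -> (chrom, 1-based TSS)
    gene_site: dict[str, int]  # gene -> 1-based planted mutation point
    bin_size: int

    def gene_bin(self, gene: str) -> int:
        return (self.gene_tss[gene][1] - 1) // self.bin_size

    @property
    def planted_genes(self) -> set[str]:
        return {g for h in self.hotspots for g in h.genes}

    def truth_groups(self) -> list[list[str]]:
        return [list(h.genes) for h in self.hotspots]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "bin_size": self.bin_size,
            "hotspots": [
                {
                    "hotspot_id": h.hotspot_id,
                    "chrom": h.chrom,
                    "genes": h.genes,
                    "bin_lo": h.bin_lo,
                    "bin_hi": h.bin_hi,
                    "mut_type": TYPE_ORDER[h.mut_type],
                    "motif": h.motif,
                }
                for h in self.hotspots
            ],
            "gene_tss": {g: [c, t] for g, (c, t) in sorted(self.gene_tss.items())},
            "gene_site": dict(sorted(self.gene_site.items())),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            doc = json.load(fh)
        hotspots = [
            Hotspot(
                hotspot_id=h["hotspot_id"],
                chrom=h["chrom"],
                genes=list(h["genes"]),
                bin_lo=int(h["bin_lo"]),
                bin_hi=int(h["bin_hi"]),
                mut_type=TYPE_ORDER.index(h["mut_type"]),
                motif=h["motif"],
            )
            for h in doc["hotspots"]
        ]
        return cls(
            hotspots=hotspots,
            gene_tss={g: (c, int(t)) for g, (c, t) in doc["gene_tss"].items()},
            gene_site={g: int(s) for g, s in doc["gene_site"].items()},
            bin_size=int(doc["bin_size"]),
        )


def _streams(cfg: SyntheticConfig) -> dict[str, np.random.Generator]:
    names = ("annotation", "reference", "contacts", "cohort", "ctcf",
             "pathways", "drivers")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _chrom_names(cfg: SyntheticConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]


# ---------------------------------------------------------------------------
# Annotation + truth

def generate_annotation(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Gene annotation (BED-style table) and the planted truth behind it."""
    rng = rng if rng is not None else _streams(cfg)["annotation"]
    chroms = _chrom_names(cfg)
    columns = ["gene_id", "chrom", "start", "end", "tss", "strand"]
    if cfg.n_genes == 0:
        empty = pd.DataFrame(columns=columns)
        return empty, PlantedTruth([], {}, {}, cfg.bin_size)

    sizes = (
        rng.integers(cfg.hotspot_size_min, cfg.hotspot_size_max + 1,
                     size=cfg.n_planted_hotspots)
        if cfg.n_planted_hotspots
        else np.array([], dtype=int)
    )
    # block width: at least hotspot_block_bins (TAD-scale domain), at least
    # one bin per gene
    widths = [max(cfg.hotspot_block_bins, int(s)) for s in sizes]
    per_chrom_sizes: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chroms}
    for k, (s, w) in enumerate(zip(sizes, widths)):
        per_chrom_sizes[chroms[k % len(chroms)]].append((k, int(s), w))

    # place blocks left-to-right with random gaps summing to the free bins
    block_bins: dict[int, tuple[str, int, int]] = {}
    gene_bins_of: dict[int, list[int]] = {}
    planted_bins: dict[str, set[int]] = {c: set() for c in chroms}
    for chrom in chroms:
        blocks = per_chrom_sizes[chrom]
        if not blocks:
            continue
        used = sum(w for _, _, w in blocks)
        free = cfg.bins_per_chromosome - used
        if free < len(blocks):  # keep at least 1-bin separations
            raise ConfigError(
                f"cannot place {len(blocks)} hotspot blocks on {chrom}: "
                f"{cfg.bins_per_chromosome} bins are too few"
            )
        gaps = rng.multinomial(free - len(blocks), [1.0 / (len(blocks) + 1)] * (len(blocks) + 1))
        pos = 0
        for (k, s, w), gap in zip(blocks, gaps[:-1]):
            pos += int(gap) + 1
            block_bins[k] = (chrom, pos, pos + w - 1)
            offsets = np.sort(rng.choice(w, size=s, replace=False))
            gene_bins_of[k] = [pos + int(o) for o in offsets]
            planted_bins[chrom].update(range(pos, pos + w))
            pos += w
        if pos > cfg.bins_per_chromosome:
            raise ConfigError("internal placement overflow")

    lo_off = _EDGE_MARGIN
    hi_off = cfg.bin_size - cfg.gene_length - _EDGE_MARGIN

    entries: list[tuple[str, int, bool, int]] = []  # (chrom, bin, planted, hotspot)
    for k in range(cfg.n_planted_hotspots):
        chrom, _, _ = block_bins[k]
        for b in gene_bins_of[k]:
            entries.append((chrom, b, True, k))
    n_background = cfg.n_genes - len(entries)
    free_bins = [
        (c, b)
        for c in chroms
        for b in range(cfg.bins_per_chromosome)
        if b not in planted_bins[c]
    ]
    if n_background > 0:
        replace = n_background > len(free_bins)
        pick = rng.choice(len(free_bins), size=n_background, replace=replace)
        for i in pick:
            c, b = free_bins[int(i)]
            entries.append((c, b, False, -1))

    # TSS offsets inside each bin, then global (chrom, tss) order fixes ids
    offs = rng.integers(lo_off, hi_off + 1, size=len(entries))
    site_offs = rng.integers(20, cfg.gene_length - 20, size=len(entries))
    raw = []
    for (chrom, b, planted, k), off, soff in zip(entries, offs, site_offs):
        tss = b * cfg.bin_size + int(off)  # 1-based; floor((tss-1)/bs) == b
        raw.append((chrom, tss, planted, k, int(soff)))
    raw.sort(key=lambda r: (int(r[0][3:]), r[1]))

    rows, gene_tss, gene_site = [], {}, {}
    hotspot_genes: dict[int, list[str]] = {k: [] for k in range(cfg.n_planted_hotspots)}
    for i, (chrom, tss, planted, k, soff) in enumerate(raw):
        gid = f"G{i + 1:04d}"
        rows.append((gid, chrom, tss, tss + cfg.gene_length - 1, tss, "+"))
        gene_tss[gid] = (chrom, tss)
        gene_site[gid] = tss + soff
        if planted:
            hotspot_genes[k].append(gid)

    annotation = pd.DataFrame(rows, columns=columns)
    hotspots = []
    for k in range(cfg.n_planted_hotspots):
        chrom, lo, hi = block_bins[k]
        t_idx = _COMPLEMENT_CYCLE[k % 12]
        ref_base = TYPE_ORDER[t_idx][0]
        motif_codes = rng.integers(0, 4, size=21)
        motif = "".join("ACGT"[c] for c in motif_codes)
        motif = motif[:10] + ref_base + motif[11:]
        hotspots.append(
            Hotspot(
                hotspot_id=f"HS{k + 1:02d}",
                chrom=chrom,
                genes=hotspot_genes[k],
                bin_lo=lo,
                bin_hi=hi,
                mut_type=t_idx,
                motif=motif,
            )
        )
    return annotation, PlantedTruth(hotspots, gene_tss, gene_site, cfg.bin_size)


# ---------------------------------------------------------------------------
# Reference sequence

def generate_reference(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, bytes]:
    """Uniform-random A/C/G/T chromosomes with planted flank structure.

    Every planted gene's mutation site carries its hotspot's reference
    base; with probability ``flank_conservation`` per gene, the whole 21-nt
    window around the site is the hotspot motif.
    """
    rng = rng if rng is not None else _streams(cfg)["reference"]
    chrom_len = cfg.bins_per_chromosome * cfg.bin_size
    seqs: dict[str, np.ndarray] = {}
    for chrom in _chrom_names(cfg):
        codes = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        seqs[chrom] = codes
    for h in truth.hotspots:
        ref_code = _B2I[TYPE_ORDER[h.mut_type][0]]
        motif_codes = np.array([_B2I[b] for b in h.motif], dtype=np.uint8)
        for g in h.genes:
            site = truth.gene_site[g]  # 1-based
            arr = seqs[h.chrom]
            if rng.random() < cfg.flank_conservation:
                arr[site - 11 : site + 10] = motif_codes
            arr[site - 1] = ref_code
    return {c: _BASES[a].tobytes() for c, a in seqs.items()}


def write_fasta(reference: dict[str, bytes], path: str | Path, width: int = 80) -> None:
    with open(path, "wb") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n".encode())
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + b"\n")


class ReferenceView:
    """Decode-on-slice view so bytes chromosomes behave like strings."""

    def __init__(self, reference: dict[str, bytes]):
        self._ref = reference

    def __getitem__(self, chrom: str) -> "._Contig":
        return _Contig(self._ref[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._ref


class _Contig:
    def __init__(self, data: bytes):
        self._data = data

    def __getitem__(self, sl) -> str:
        out = self._data[sl]
        return out.decode() if isinstance(out, bytes) else chr(out)

    def __len__(self) -> int:
        return len(self._data)


# ---------------------------------------------------------------------------
# Contact matrices

def generate_contact_matrices(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
    noise: str = "poisson",
) -> dict[str, ContactMatrix]:
    """Per-chromosome symmetric contact matrices.

    The expected count at bin distance d is contact_depth * (d+1)**(-decay);
    entries whose bin pair falls inside one planted block are multiplied by
    ``contact_boost`` before Poisson sampling (``noise="none"`` returns the
    expectation itself).
    """
    if cfg.bins_per_chromosome < 2:
        raise ConfigError("need at least 2 bins per chromosome")
    rng = rng if rng is not None else _streams(cfg)["contacts"]
    n = cfg.bins_per_chromosome
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    base = cfg.contact_depth * (d + 1.0) ** (-cfg.decay_exponent)
    out: dict[str, ContactMatrix] = {}
    for chrom in _chrom_names(cfg):
        mu = base.copy()
        for h in truth.hotspots:
            if h.chrom == chrom:
                sl = slice(h.bin_lo, h.bin_hi + 1)
                mu[sl, sl] *= cfg.contact_boost
        if noise == "poisson":
            upper = rng.poisson(np.triu(mu)).astype(float)
            mat = np.triu(upper) + np.triu(upper, k=1).T
        elif noise == "none":
            mat = mu
        else:
            raise ConfigError(f"unknown noise model {noise!r}")
        mask = np.zeros(n, dtype=bool)
        n_missing = int(round(cfg.missing_bin_fraction * n))
        if n_missing:
            miss = rng.choice(n, size=n_missing, replace=False)
            mask[miss] = True
            mat[:, mask] = np.nan
            mat[mask, :] = np.nan
        out[chrom] = ContactMatrix(chrom=chrom, bin_size=cfg.bin_size, matrix=mat, mask=mask)
    return out


# ---------------------------------------------------------------------------
# Mutation cohort

def _random_alt(rng: np.random.Generator, ref: str) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[int(rng.integers(0, 3))]


def generate_mutation_cohort(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    reference: dict[str, bytes],
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """MAF-like mutation table with planted co-mutation structure.

    Per sample, each hotspot fires with probability ``comut_prob``; a
    firing hotspot mutates every member gene once — at the gene's fixed
    site with the hotspot's substitution type (probability
    ``signature_concordance``) or at a random in-gene position with a
    uniform random substitution otherwise.  Background genes mutate
    independently at ``background_mut_prob`` per sample, at random
    positions.  Reference alleles always match the reference sequence and
    alt never equals ref.
    """
    rng = rng if rng is not None else _streams(cfg)["cohort"]
    planted = truth.planted_genes
    bg_rows = annotation[~annotation["gene_id"].isin(planted)]
    bg_genes = list(bg_rows["gene_id"])
    bg_chrom = dict(zip(bg_rows["gene_id"], bg_rows["chrom"]))
    bg_tss = dict(zip(bg_rows["gene_id"], bg_rows["tss"]))
    samples = [f"S{j + 1:04d}" for j in range(cfg.n_samples)]
    rows = []

    def _base_at(chrom: str, pos: int) -> str:
        return chr(reference[chrom][pos - 1])

    for sample in samples:
        for h in truth.hotspots:
            if rng.random() >= cfg.comut_prob:
                continue
            for g in h.genes:
                if rng.random() < cfg.signature_concordance:
                    pos = truth.gene_site[g]
                    ref, alt = TYPE_ORDER[h.mut_type].split(">")
                else:
                    tss = truth.gene_tss[g][1]
                    pos = int(rng.integers(tss, tss + cfg.gene_length))
                    ref = _base_at(h.chrom, pos)
                    alt = _random_alt(rng, ref)
                rows.append((sample, g, h.chrom, pos, ref, alt))
        if bg_genes and cfg.background_mut_prob > 0:
            hits = np.flatnonzero(rng.random(len(bg_genes)) < cfg.background_mut_prob)
            for i in hits:
                g = bg_genes[int(i)]
                chrom = bg_chrom[g]
                tss = int(bg_tss[g])
                pos = int(rng.integers(tss, tss + cfg.gene_length))
                ref = _base_at(chrom, pos)
                alt = _random_alt(rng, ref)
                rows.append((sample, g, chrom, pos, ref, alt))
    return pd.DataFrame(rows, columns=list(MAF_COLUMNS))


def records_from_frame(df: pd.DataFrame) -> list[MutationRecord]:
    """In-memory counterpart of :func:`schpipe.comut.read_mutations`."""
    return [
        MutationRecord(
            sample_id=str(r.Tumor_Sample_Barcode),
            gene_id=str(r.Hugo_Symbol),
            chrom=str(r.Chromosome),
            position=int(r.Start_Position),
            ref=str(r.Reference_Allele),
            alt=str(r.Tumor_Seq_Allele2),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# CTCF track, pathways, drivers

def generate_ctcf_track(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
    boost_halfwidth: int = 2000,
) -> SignalTrack:
    """Noisy baseline bedGraph, boosted within +/- 2 kb of planted TSSs."""
    rng = rng if rng is not None else _streams(cfg)["ctcf"]
    chrom_len = cfg.bins_per_chromosome * cfg.bin_size
    step = cfg.ctcf_interval
    data = {}
    boosted: dict[str, list[tuple[int, int]]] = {}
    for g in truth.planted_genes:
        chrom, tss = truth.gene_tss[g]
        boosted.setdefault(chrom, []).append(
            (max(0, tss - 1 - boost_halfwidth), min(chrom_len, tss - 1 + boost_halfwidth))
        )
    for chrom in _chrom_names(cfg):
        starts = np.arange(0, chrom_len, step, dtype=np.int64)
        ends = np.minimum(starts + step, chrom_len)
        vals = rng.lognormal(mean=0.0, sigma=cfg.ctcf_noise_sd, size=len(starts))
        for lo, hi in boosted.get(chrom, []):
            sel = (ends > lo) & (starts < hi)
            vals[sel] *= cfg.ctcf_boost
        data[chrom] = (starts, ends, vals)
    return SignalTrack(data=data)


def generate_pathways(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict[str, set[str]]:
    """GMT-style pathway sets, a fraction of hotspots embedded whole."""
    rng = rng if rng is not None else _streams(cfg)["pathways"]
    all_genes = list(annotation["gene_id"])
    pathways: dict[str, set[str]] = {}
    k = 0
    for h in truth.hotspots:
        if rng.random() < cfg.pathway_fraction:
            k += 1
            members = set(h.genes)
            others = [g for g in all_genes if g not in members]
            extra = cfg.pathway_size - len(members)
            if extra > 0 and others:
                pick = rng.choice(len(others), size=min(extra, len(others)), replace=False)
                members |= {others[int(i)] for i in pick}
            pathways[f"PW{k:03d}"] = members
    while len(pathways) < cfg.n_pathways and all_genes:
        k += 1
        size = min(cfg.pathway_size, len(all_genes))
        pick = rng.choice(len(all_genes), size=size, replace=False)
        pathways[f"PW{k:03d}"] = {all_genes[int(i)] for i in pick}
    return pathways


def generate_drivers(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Driver list biased toward planted genes."""
    rng = rng if rng is not None else _streams(cfg)["drivers"]
    planted = truth.planted_genes
    drivers: set[str] = set()
    for g in sorted(annotation["gene_id"]):
        p = cfg.driver_planted_fraction if g in planted else cfg.driver_background_fraction
        if rng.random() < p:
            drivers.add(g)
    return drivers


# ---------------------------------------------------------------------------
# Bundled dataset

@dataclass
class SyntheticDataset:
    cfg: SyntheticConfig
    truth: PlantedTruth
    annotation: pd.DataFrame
    reference: dict[str, bytes]
    contact_maps: dict[str, ContactMatrix]
    mutations: pd.DataFrame
    ctcf: SignalTrack
    pathways: dict[str, set[str]]
    drivers: set[str]

    def mutation_records(self) -> list[MutationRecord]:
        return records_from_frame(self.mutations)

    def reference_view(self) -> ReferenceView:
        return ReferenceView(self.reference)


def simulate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle for one seeded configuration."""
    rngs = _streams(cfg)
    annotation, truth = generate_annotation(cfg, rngs["annotation"])
    reference = generate_reference(cfg, truth, rngs["reference"])
    contacts = generate_contact_matrices(cfg, truth, rngs["contacts"])
    mutations = generate_mutation_cohort(cfg, truth, reference, annotation, rngs["cohort"])
    ctcf = generate_ctcf_track(cfg, truth, rngs["ctcf"])
    pathways = generate_pathways(cfg, truth, annotation, rngs["pathways"])
    drivers = generate_drivers(cfg, truth, annotation, rngs["drivers"])
    return SyntheticDataset(
        cfg=cfg,
        truth=truth,
        annotation=annotation,
        reference=reference,
        contact_maps=contacts,
        mutations=mutations,
        ctcf=ctcf,
        pathways=pathways,
        drivers=drivers,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Persist every generated artifact; returns the path map."""
    from .enrichment import write_gmt
    from .io import write_annotation_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "hic").mkdir(exist_ok=True)
    paths = {
        "mutations": str(out / "mutations.tsv"),
        "annotation": str(out / "annotation.bed"),
        "fasta": str(out / "reference.fa"),
        "ctcf": str(out / "ctcf.bedgraph"),
        "gmt": str(out / "pathways.gmt"),
        "drivers": str(out / "drivers.txt"),
        "truth": str(out / "truth.json"),
        "hic_dir": str(out / "hic"),
        "config": str(out / "config.yaml"),
    }
    ds.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    write_annotation_bed(ds.annotation, paths["annotation"])
    write_fasta(ds.reference, paths["fasta"])
    write_bedgraph(ds.ctcf, paths["ctcf"])
    write_gmt(ds.pathways, paths["gmt"])
    with open(paths["drivers"], "w") as fh:
        for g in sorted(ds.drivers):
            fh.write(g + "\n")
    ds.truth.to_json(paths["truth"])
    for chrom, cm in ds.contact_maps.items():
        write_contact_matrix(cm, Path(paths["hic_dir"]) / f"{chrom}.dense.tsv", "dense")
        write_contact_matrix(cm, Path(paths["hic_dir"]) / f"{chrom}.coo.tsv", "coo")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(ds.cfg.to_dict(), fh, sort_keys=True)
    return paths
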