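"""Configuration objects for the simulator and the end-to-end pipeline.

The simulator is parameterized by :class:`SyntheticConfig`.  Its defaults
describe the reference planted scenario used throughout the test battery:
two chromosomes of 250 bins at 40 kb, 300 genes, 40 tumor samples, five
planted hotspots of 4-8 genes whose Hi-C blocks are boosted 5-fold, a
per-sample co-mutation probability of 0.8 inside a hotspot against a 0.02
background mutation rate, and strong (0.8) mutational-signature concordance
and flank conservation inside hotspots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort + Hi-C generator.

    Probabilities must lie in [0, 1]; counts must be positive.  A fixed
    ``seed`` makes every generated artifact byte-identical between runs.
    """

    seed: int = 0
    n_chromosomes: int = 2
    bins_per_chromosome: int = 250
    bin_size: int = 40_000
    decay_exponent: float = 1.0
    #: expected Hi-C count on the main diagonal; off-diagonal means decay
    #: as contact_depth * (d+1)**(-decay_exponent)
    contact_depth: float = 100.0
    n_genes: int = 300
    gene_length: int = 1_000
    n_samples: int = 40
    n_planted_hotspots: int = 5
    hotspot_size_min: int = 4
    hotspot_size_max: int = 8
    #: minimum width (in bins) of a planted high-contact block; hotspots
    #: emulate TAD-scale contact domains (~0.5 Mb at 40 kb bins) that
    #: contain the co-mutated genes, so the block is at least this wide
    #: even when it holds fewer genes
    hotspot_block_bins: int = 12
    contact_boost: float = 5.0
    comut_prob: float = 0.8
    background_mut_prob: float = 0.02
    signature_concordance: float = 0.8
    flank_conservation: float = 0.8
    ctcf_boost: float = 3.0
    ctcf_interval: int = 200
    ctcf_noise_sd: float = 0.5
    #: fraction of planted hotspots embedded in a single pathway gene set
    pathway_fraction: float = 0.8
    n_pathways: int = 20
    pathway_size: int = 15
    driver_planted_fraction: float = 0.5
    driver_background_fraction: float = 0.05
    missing_bin_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "comut_prob": self.comut_prob,
            "background_mut_prob": self.background_mut_prob,
            "signature_concordance": self.signature_concordance,
            "flank_conservation": self.flank_conservation,
            "pathway_fraction": self.pathway_fraction,
            "driver_planted_fraction": self.driver_planted_fraction,
            "driver_background_fraction": self.driver_background_fraction,
            "missing_bin_fraction": self.missing_bin_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "bins_per_chromosome": self.bins_per_chromosome,
            "bin_size": self.bin_size,
            "n_samples": self.n_samples,
            "gene_length": self.gene_length,
            "ctcf_interval": self.ctcf_interval,
        }
        for name, c in counts.items():
            if c <= 0:
                raise ConfigError(f"{name} must be positive, got {c}")
        if self.n_genes < 0 or self.n_planted_hotspots < 0:
            raise ConfigError("n_genes and n_planted_hotspots must be >= 0")
        if self.n_planted_hotspots > 0:
            if not 1 <= self.hotspot_size_min <= self.hotspot_size_max:
                raise ConfigError("need 1 <= hotspot_size_min <= hotspot_size_max")
            if self.hotspot_size_max * self.n_planted_hotspots > self.n_genes:
                raise ConfigError(
                    "hotspot_size_max exceeds n_genes / n_planted_hotspots"
                )
        if self.contact_boost <= 0 or self.ctcf_boost <= 0:
            raise ConfigError("boost factors must be positive")
        if self.contact_depth <= 0:
            raise ConfigError("contact_depth must be positive")
        if self.gene_length + 200 >= self.bin_size:
            raise ConfigError("bin_size must exceed gene_length + 200")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown simulate config keys: {sorted(extra)}")
        return cls(**d)


#: Hamming-similarity thresholds scanned during co-mutation cluster selection.
DEFAULT_THRESHOLD_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is set (the pipeline generates its own inputs) or
    the explicit input paths are set.  ``alpha_intra_inter`` is the 0.005
    significance cutoff applied to the intra- vs inter-class contact
    comparison; ``enrichment_cutoffs`` is the grid of cluster p-value
    cutoffs for the pathway enrichment-fraction curves.
    """

    simulate: SyntheticConfig | None = None
    mutations: str | None = None
    hic_dir: str | None = None
    annotation: str | None = None
    fasta: str | None = None
    gmt: str | None = None
    drivers: str | None = None
    ctcf: str | None = None
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    alpha_intra_inter: float = 0.005
    enrichment_cutoffs: tuple[float, ...] = (0.001, 0.01, 0.05)
    enrichment_report_cutoff: float = 0.01
    hic_cutoff_policy: str = "noise"
    hic_cutoff_value: float | None = None
    conservation_resamples: int = 200
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha_intra_inter < 1:
            raise ConfigError("alpha_intra_inter must be in (0, 1)")
        if self.simulate is None and self.mutations is None:
            raise ConfigError("config needs a simulate block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        kwargs: dict[str, Any] = {}
        if sim is not None:
            kwargs["simulate"] = SyntheticConfig.from_dict(sim)
        known = {f.name for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in known:
                raise ConfigError(f"unknown run config key: {key}")
            if key in ("threshold_grid", "enrichment_cutoffs"):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d: dict[str, Any] = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["threshold_grid"] = list(self.threshold_grid)
        d["enrichment_cutoffs"] = list(self.enrichment_cutoffs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
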