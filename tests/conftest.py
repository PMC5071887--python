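import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from schpipe import SyntheticConfig, simulate
from schpipe.hic import ContactMatrix


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A fast planted scenario used by several integration tests."""
    return SyntheticConfig(
        seed=7,
        n_chromosomes=2,
        bins_per_chromosome=80,
        bin_size=5_000,
        n_genes=80,
        n_samples=30,
        n_planted_hotspots=3,
        hotspot_size_min=4,
        hotspot_size_max=5,
        hotspot_block_bins=8,
        background_mut_prob=0.05,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_contact(matrix, chrom="chr1", bin_size=40_000, mask=None) -> ContactMatrix:
    matrix = np.asarray(matrix, dtype=float)
    if mask is None:
        mask = np.zeros(matrix.shape[0], dtype=bool)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=matrix, mask=mask)


def toy_annotation(entries) -> pd.DataFrame:
    """entries: iterable of (gene_id, chrom, tss)."""
    rows = [(g, c, t, t + 999, t, "+") for g, c, t in entries]
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "tss", "strand"]
    )
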