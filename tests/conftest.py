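"""Shared fixtures: synthetic genomes, a band-annotated two-chromosome
human-scale genome, and tiny hand-built genomes for arithmetic tests."""

from importlib import resources

import numpy as np
import pandas as pd
import pytest

from embryoscreen import GenomeModel, default_genome_spec, make_synthetic_genome
from embryoscreen.io import read_cytoband

HG18_CHR1_LEN = 247_249_719
HG18_CHR2_LEN = 242_951_149


@pytest.fixture(scope="session")
def genome300():
    """The default ~300 Mb synthetic genome at 1 Mb bins."""
    return make_synthetic_genome(default_genome_spec(), seed=7)


@pytest.fixture(scope="session")
def band_fixture_path():
    path = resources.files("embryoscreen") / "data" / (
        "cytoband_hg18like_chr1_chr2_synthetic.txt"
    )
    return str(path)


@pytest.fixture(scope="session")
def hg18_genome(band_fixture_path):
    """chr1/chr2 at real hg18 lengths with the synthetic band fixture."""
    bands = read_cytoband(band_fixture_path)
    chroms = (("chr1", HG18_CHR1_LEN), ("chr2", HG18_CHR2_LEN))
    bin_size = 1_000_000
    n_bins = sum(-(-l // bin_size) for _, l in chroms)
    return GenomeModel(
        chromosomes=chroms,
        bin_size=bin_size,
        gc_per_bin=np.full(n_bins, 0.45),
        cytobands=bands,
    )


def tiny_genome(n_bins=10, bin_size=20, gc=None, with_sex=False, cytobands=None):
    """One-autosome toy genome for exact-arithmetic tests."""
    chroms = [("c1", n_bins * bin_size)]
    total = n_bins
    if with_sex:
        chroms += [("chrX", n_bins * bin_size), ("chrY", n_bins * bin_size)]
        total = 3 * n_bins
    if gc is None:
        gc = np.full(total, 0.5)
    return GenomeModel(
        chromosomes=tuple(chroms), bin_size=bin_size, gc_per_bin=gc,
        cytobands=cytobands,
    )


@pytest.fixture
def make_tiny_genome():
    return tiny_genome
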