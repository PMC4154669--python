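import pandas as pd
import pytest

from ernascan.genomic_io import BED6_COLUMNS, ReadSet
from ernascan.synthetic_data import SimConfig, simulate_bundle


def make_reads(rows, tissue="t", library_size=None):
    """ReadSet from (chrom, start, end, strand) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df.insert(3, "name", [f"r{i}" for i in range(len(df))])
    df.insert(4, "score", 1)
    df = df[BED6_COLUMNS]
    return ReadSet(df, library_size=library_size if library_size is not None
                   else len(df), tissue=tissue)


def make_intervals(rows):
    """BED6 DataFrame from (chrom, start, end) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"iv{i}" for i in range(len(df))]
    df["score"] = 0.0
    df["strand"] = "."
    return df


@pytest.fixture(scope="session")
def poisson_config():
    return SimConfig(noise="poisson", seed=11)


@pytest.fixture(scope="session")
def poisson_bundle(poisson_config):
    """Study-condition fixture with exact Poisson counts (shared, read-only)."""
    return simulate_bundle(poisson_config)


@pytest.fixture
def small_config():
    """A light-weight configuration for fast pipeline smoke tests."""
    return SimConfig(
        chromosome_lengths=(("chr1", 400_000), ("chr2", 400_000)),
        n_genes=10, n_rrna=1, n_specific_loci=20, n_nonspecific_loci=20,
        noise="poisson", min_gap=2_000, phastcons_background_n=80,
        cage_background_n=10, seed=5)
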