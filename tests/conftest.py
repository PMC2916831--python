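import numpy as np
import pandas as pd
import pytest

from breadthatlas.config import SimConfig
from breadthatlas.features import GeneAnnotation
from breadthatlas.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down atlas keeping the default 8 tissues x 5 replicates."""
    return SimConfig(
        n_genes=400,
        n_negative_controls=50,
        n_ortholog_triplets=300,
        n_chromosomes=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_files(small_dataset, tmp_path_factory):
    from breadthatlas.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    return write_dataset(small_dataset, outdir)


def make_annotation(genes, exons=None, cds=None) -> GeneAnnotation:
    """Build a GeneAnnotation from (gene_id, chrom, strand, start, end) rows."""
    table = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "strand", "start", "end"]
    ).set_index("gene_id")
    exons = exons or {g: [(r["start"], r["end"])] for g, r in table.iterrows()}
    cds = cds or {g: [] for g in table.index}
    return GeneAnnotation(table, exons, cds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
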