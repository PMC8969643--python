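"""Shared fixtures: simulated datasets at several scales.

The default-scale dataset (4 chromosomes x 2 Mb, ~25 contigs each,
1000 cells at hit rate 0.13 and allele error 0.005) is the package's
standard study condition; smaller datasets exist for fast unit tests.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from spermlink import CellAlleleMatrix, Config, SpermLinkageModel
from spermlink import synthdata as sd

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def recovery_dataset():
    """Default study conditions, haploid cells only."""
    return sd.simulate_dataset(seed=11, doublet_fraction=0.0, diploid_fraction=0.0)


@pytest.fixture(scope="session")
def recovery_results(recovery_dataset):
    ds = recovery_dataset
    return SpermLinkageModel(ds.matrix, ds.contigs.lengths).fit()


@pytest.fixture(scope="session")
def doublet_dataset():
    """Default study conditions with a 5% doublet fraction."""
    return sd.simulate_dataset(seed=12, doublet_fraction=0.05, diploid_fraction=0.0)


@pytest.fixture(scope="session")
def doublet_results(doublet_dataset):
    ds = doublet_dataset
    return SpermLinkageModel(ds.matrix, ds.contigs.lengths).fit()


@pytest.fixture(scope="session")
def small_dataset():
    """Two 500 kb chromosomes, 200 cells; fast unit-test scale."""
    return sd.simulate_dataset(
        n_chrom=2,
        chrom_len_bp=500_000,
        n_cells=200,
        doublet_fraction=0.0,
        diploid_fraction=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def smallgroup_dataset():
    """Three short chromosomes of ~5 contigs each: every linkage group is
    small enough for the exhaustive order/orientation oracle."""
    return sd.simulate_dataset(
        n_chrom=3,
        chrom_len_bp=500_000,
        mean_contig_len_bp=100_000,
        n_cells=400,
        doublet_fraction=0.0,
        diploid_fraction=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def smallgroup_results(smallgroup_dataset):
    ds = smallgroup_dataset
    return SpermLinkageModel(ds.matrix, ds.contigs.lengths).fit()


def make_matrix(entries, n_markers, n_cells, contig="ctg1", spacing=10):
    """Small CellAlleleMatrix from {(marker, cell): value} entries; markers
    ``spacing`` bp apart on one contig."""
    markers = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(1, n_markers + 1) * spacing,
            "ref": "A",
            "alt": "C",
        }
    )
    X = sparse.dok_matrix((n_markers, n_cells), dtype=np.int8)
    for (i, j), v in entries.items():
        X[i, j] = v
    return CellAlleleMatrix(
        markers=markers,
        barcodes=[f"c{j}" for j in range(n_cells)],
        X=X.tocsr(),
    )


@pytest.fixture
def tiny_matrix_factory():
    return make_matrix
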