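import numpy as np
import pytest

from txstress import GeneRecord, build_catalog
from txstress.synth import CatalogConfig, make_catalog


@pytest.fixture
def two_gene_catalog():
    """Two genes, expression 30/10 -> alpha (0.75, 0.25), on a toy genome."""
    records = [
        GeneRecord("gA", 100_000, 30.0),
        GeneRecord("gB", 10_000, 10.0),
    ]
    return build_catalog(records, genome_length_L=3_200_000_000)


@pytest.fixture
def single_gene_full_genome():
    """One gene spanning the whole genome: q = 1/4, alpha = 1."""
    return build_catalog([GeneRecord("g", 1000, 5.0)], genome_length_L=1000)


def random_toy_catalog(rng: np.random.Generator, n_genes: int = 50):
    """Small random catalog for oracle comparisons (q large enough to hit)."""
    lengths = rng.integers(5_000, 200_000, size=n_genes)
    expr = rng.lognormal(0.0, 1.0, size=n_genes)
    L = int(lengths.sum() * rng.uniform(1.5, 4.0))
    records = [
        GeneRecord(f"g{i}", int(l), float(e))
        for i, (l, e) in enumerate(zip(lengths, expr))
    ]
    return build_catalog(records, L)


@pytest.fixture(scope="session")
def mouse_like_catalog():
    """Mouse-liver-like synthetic catalog (9,000 genes, L = 2.65 Gb)."""
    return make_catalog(CatalogConfig(), seed=101)


@pytest.fixture(scope="session")
def small_catalog():
    """Cheap 500-gene catalog for tests that only need realistic shape."""
    return make_catalog(
        CatalogConfig(n_genes=500, genome_length_L=400_000_000), seed=77
    )
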