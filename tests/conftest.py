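import numpy as np
import pytest

from phantomgs import MosaicConfig, filter_maf, simulate_genotypes
from phantomgs.geno_io import MarkerMatrix


@pytest.fixture(scope="session")
def mosaic():
    """A mid-sized filtered mosaic panel shared by kernel/model tests."""
    g = simulate_genotypes(
        MosaicConfig(
            n_lines=150, n_founders=20, p_sites=2500, chrom_length_bp=1_200_000,
            seed=11,
        )
    )
    return filter_maf(g, 0.01)


@pytest.fixture(scope="session")
def two_pop():
    """Two strongly differentiated subpopulations (constructed, separable)."""
    from phantomgs.geno_io import orient_minor

    rng = np.random.default_rng(5)
    n_per, p = 40, 120
    f0 = np.where(rng.random(p) < 0.5, 0.45, 0.05)
    f1 = np.where(rng.random(p) < 0.5, 0.45, 0.05)
    values = np.vstack([
        rng.random((n_per, p)) < f0,
        rng.random((n_per, p)) < f1,
    ]).astype(np.int8)
    ids = np.array(
        [f"S0_L{i:03d}" for i in range(n_per)]
        + [f"S1_L{i:03d}" for i in range(n_per)]
    )
    pos = np.sort(rng.choice(500_000, size=p, replace=False)) + 1
    g = MarkerMatrix(orient_minor(values), ids, np.full(p, "1"), pos)
    return filter_maf(g, 0.01)


@pytest.fixture
def tiny_matrix():
    """Handmade 4x5 matrix on two chromosomes."""
    values = np.array(
        [
            [1, 0, 0, 1, 0],
            [0, 1, 0, 1, 1],
            [0, 0, 1, 0, 0],
            [1, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return MarkerMatrix(
        values=values,
        accession_ids=np.array(["a", "b", "c", "d"]),
        chrom=np.array(["1", "1", "1", "2", "2"]),
        pos=np.array([100, 250, 400, 50, 300]),
    )
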