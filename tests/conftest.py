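"""Shared fixtures: small synthetic datasets with known generating truth."""

import numpy as np
import pytest

from karstdemog import GenotypeMatrix, LocusRecord, PopulationMap
from karstdemog.synthetic_data import (
    panmictic_fixture,
    reduced_mle_fixture,
    toy_filter_matrix,
    two_island_fixture,
)


@pytest.fixture(scope="session")
def toy_filter():
    """3-population toy matrix with staged missingness (fixture a)."""
    return toy_filter_matrix(seed=101)


@pytest.fixture(scope="session")
def island():
    """Two-island near-equilibrium dataset, Nm = 1 each way (fixture b)."""
    return two_island_fixture(seed=5)


@pytest.fixture(scope="session")
def panmictic():
    """Panmictic population mislabelled as two clusters (fixture c)."""
    return panmictic_fixture(seed=6)


@pytest.fixture(scope="session")
def reduced_mle():
    """Best-model history at full sample sizes, 300 loci (fixture d)."""
    return reduced_mle_fixture(seed=42, n_loci=300)


@pytest.fixture
def tiny_matrix():
    """5 samples × 4 SNPs with hand-readable genotypes, no missing data."""
    calls = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 1],
            [0, 2, 0, 1],
            [2, 1, 1, 1],
            [1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    loci = [LocusRecord(locus_id=f"L{j}", site_index=j) for j in range(4)]
    samples = [f"s{i}" for i in range(5)]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    popmap = PopulationMap(
        {"s0": "P1", "s1": "P1", "s2": "P2", "s3": "P2", "s4": "P2"},
        {"P1": "I", "P2": "II"},
    )
    return gm, popmap
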