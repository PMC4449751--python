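import numpy as np
import pytest

from ibrkit import (
    GeneticSimParams,
    LandscapeParams,
    Raster,
    place_groups,
    simulate_genotypes,
    simulate_landscape,
)
from ibrkit.genepop import GenotypeTable


@pytest.fixture()
def small_raster() -> Raster:
    """Deterministic 3-value strip used in transformation hand examples."""
    return Raster(values=np.array([[1.0, 2.0, 4.0]]), cell_size=300.0)


@pytest.fixture(scope="session")
def landscape() -> Raster:
    return simulate_landscape(
        LandscapeParams(nrows=30, ncols=30, cell_size=1000.0,
                        correlation_range=8000.0, value_range=(1.0, 100.0),
                        seed=7)
    )


@pytest.fixture(scope="session")
def focal_groups(landscape):
    return place_groups(landscape, 10, min_separation=4000.0, seed=8)


@pytest.fixture(scope="session")
def genotypes_37() -> GenotypeTable:
    """A microsatellite-panel-sized table: 37 groups, 14 loci, ~2% missing."""
    params = GeneticSimParams(n_groups=37, loci=14, alleles_per_locus=8,
                              individuals_per_group=15, differentiation=0.08,
                              missing_rate=0.02, seed=42)
    return simulate_genotypes([f"g{k:02d}" for k in range(1, 38)], params)


def two_group_table(counts1: tuple[int, int], counts2: tuple[int, int]) -> GenotypeTable:
    """One-locus two-group table with exact biallelic allele counts (of 20)."""

    def calls(counts):
        copies = [1] * counts[0] + [2] * counts[1]
        return [(copies[i], copies[i + 1]) for i in range(0, len(copies), 2)]

    c1, c2 = calls(counts1), calls(counts2)
    return GenotypeTable(
        individual_ids=[f"i{k}" for k in range(len(c1) + len(c2))],
        group_ids=["g1"] * len(c1) + ["g2"] * len(c2),
        locus_names=["L1"],
        calls=np.array(c1 + c2)[:, None, :],
    )
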