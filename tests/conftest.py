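import numpy as np
import pytest

import haplomix as hm


@pytest.fixture(scope="session")
def toy_maps():
    """Two uniform 20-cM chromosomes of 20 Mb."""
    return hm.make_genome_maps(n_chrom=2, cm_per_chrom=20.0, bp_per_chrom=20_000_000)


@pytest.fixture(scope="session")
def small_sources(toy_maps):
    """Two differentiated source panels sharing 400 sites."""
    return hm.simulate_source_panels(
        2, 0.1, n_snps=400, n_haps=20, maps=toy_maps, names=["A", "B"], seed=11
    )


@pytest.fixture(scope="session")
def small_admixed(small_sources):
    """A 10-diploid cohort, 30% A / 70% B, 10 generations ago."""
    panel, truth = hm.simulate_admixed_population(
        small_sources, mix={"A": 0.3, "B": 0.7}, n_gen=10, n_ind=10, seed=12
    )
    return panel, truth


@pytest.fixture(scope="session")
def tiny_panel():
    """Hand-built 4-haploid, 6-site panel on one chromosome."""
    haps = np.array(
        [
            [0, 1, 0, 1, 0, 1],
            [1, 1, 0, 0, 1, 0],
            [0, 0, 1, 1, 0, 1],
            [1, 0, 1, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    pos = np.array([10, 200_000, 500_000, 1_000_000, 1_500_000, 1_900_000])
    return hm.HaplotypePanel(
        haps=haps,
        positions=pos,
        chrom=np.full(6, "1"),
        cm=pos / 1e6,
        sample_ids=["s0", "s1"],
        groups=np.array(["g0", "g0", "g1", "g1"]),
    )
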