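import pytest

from strassign import (
    Locality,
    MultilocusGenotype,
    ReferenceDatabase,
    SimulationConfig,
    simulate_reference,
)


@pytest.fixture
def tiny_db():
    """Two highly differentiated localities with near-disjoint alleles."""
    loci = ["L1", "L2"]
    locs = [Locality("north", cluster_id="A"), Locality("south", cluster_id="B")]
    inds = [
        MultilocusGenotype("n1", {"L1": (100, 100), "L2": (200, 202)}, "north"),
        MultilocusGenotype("n2", {"L1": (100, 102), "L2": (200, 200)}, "north"),
        MultilocusGenotype("n3", {"L1": (102, 102), "L2": (202, 202)}, "north"),
        MultilocusGenotype("s1", {"L1": (110, 110), "L2": (210, 212)}, "south"),
        MultilocusGenotype("s2", {"L1": (110, 112), "L2": (210, 210)}, "south"),
        MultilocusGenotype("s3", {"L1": (112, 112), "L2": (212, 212)}, "south"),
    ]
    return ReferenceDatabase(loci, locs, inds)


@pytest.fixture(scope="session")
def sim_default():
    """The default study-shaped synthetic fixture (3 clusters, 15 localities,
    180 reference individuals, 10 loci)."""
    return simulate_reference(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """A small strongly structured fixture for MCMC-heavy tests."""
    cfg = SimulationConfig(
        n_clusters=3,
        localities_per_cluster=(2, 2, 2),
        individuals_per_locality=10,
        n_loci=8,
        alleles_per_locus=6,
        cluster_drift=0.25,
        locality_drift=0.02,
        seed=7,
    )
    return simulate_reference(cfg)
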