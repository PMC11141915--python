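import numpy as np
import pandas as pd
import pytest

from chromoevo.genome import default_genome
from chromoevo.karyosim import (BranchEvents, EvolutionScenario, RegionSpec,
                                ROOT_CLONE, default_scenario, simulate_scenario)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def chrom_lengths(genome):
    return {c.name: float(c.length) for c in genome.chromosomes}


@pytest.fixture(scope="session")
def dataset(genome):
    """Default two-region patient (classic + dedifferentiated), purity 0.7."""
    return simulate_scenario(default_scenario(), genome, seed=7)


@pytest.fixture(scope="session")
def four_region_scenario():
    """Caterpillar-ish clone tree sampled by four pure regions: trunk clone
    c1, descendant c2, and two children c3/c4 of c2."""
    branches = (
        ("c1", ROOT_CLONE, BranchEvents(
            monosomies=("1", "2", "6", "10", "13", "17", "21"),
            drivers=("TP53L",), passenger_rate=30.0)),
        ("c2", "c1", BranchEvents(passenger_rate=25.0)),
        ("c3", "c2", BranchEvents(passenger_rate=25.0)),
        ("c4", "c2", BranchEvents(drivers=("PTENL",), passenger_rate=25.0)),
    )
    regions = tuple(
        RegionSpec(rid, {cid: 1.0}, purity=0.7, coverage=100.0,
                   subcategory="classic")
        for rid, cid in (("R1", "c1"), ("R2", "c2"), ("R3", "c3"),
                         ("R4", "c4")))
    return EvolutionScenario(branches=branches, regions=regions)


def flat_sites(n=500, sigma=0.05, seed=0, chrom="1"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chrom": chrom, "position": np.arange(n) * 1.0,
        "logr": rng.normal(0.0, sigma, n),
        "logor": rng.normal(0.0, sigma, n),
        "logor_var": sigma ** 2,
    })
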