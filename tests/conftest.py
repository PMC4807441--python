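import numpy as np
import pandas as pd
import pytest

from hybridzone.io import GenotypeTable
from hybridzone.simulate import (SimulationConfig, SiteSpec,
                                 fixed_difference_loci, simulate_parental_pools)


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Two sites, two codominant loci, four individuals, mito typed."""
    data = pd.DataFrame({
        "individual_id": ["a1", "a2", "b1", "b2"],
        "site_id": [1, 1, 2, 2],
        "sex": ["F", "M", "", ""],
        "year": [2008, 2008, 2008, 2008],
        "mito": ["S", "S", "N", "N"],
        "LocA.a1": [151, 151, 155, 155],
        "LocA.a2": [155, 151, 155, 151],
        "LocB.a1": [103, 103, 107, 0],
        "LocB.a2": [103, 107, 107, 0],
    })
    sites = pd.DataFrame({"site_id": [1, 2], "name": ["south", "north"],
                          "distance_km": [0.0, 100.0],
                          "lat": [31.0, 43.0], "lon": [-81.0, -70.0]})
    return GenotypeTable(data, ["LocA", "LocB"], sites)


@pytest.fixture(scope="session")
def parental_pools():
    """30+30 pure parental individuals at 10 fixed-difference loci."""
    return simulate_parental_pools(fixed_difference_loci(10), 30, seed=1)


@pytest.fixture(scope="session")
def two_pool_with_f1():
    """Parental pools plus a pure-F1 site, 20 fixed-difference loci."""
    loci = fixed_difference_loci(20)
    sites = [SiteSpec(1, 0.0, 25, {"P_S": 1.0}),
             SiteSpec(2, 500.0, 25, {"F1": 1.0}),
             SiteSpec(3, 1000.0, 25, {"P_N": 1.0})]
    from hybridzone.simulate import simulate_hybrid_zone
    return simulate_hybrid_zone(SimulationConfig(loci, sites, seed=3))
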