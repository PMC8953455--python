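import numpy as np
import pandas as pd
import pytest

from admixscan import (
    GeneticMap,
    HaplotypeMatrix,
    LocalAncestryTrack,
    SimScenario,
    SiteTable,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small admixed cohort shared by read-only tests."""
    scenario = SimScenario(n_admixed=30, n_ref=30, m_sites=3000,
                           contig_length=6_000_000, f_div=0.1, seed=7)
    return simulate_bundle(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_sites():
    pos = np.arange(1, 11) * 100
    return SiteTable.from_arrays(["1"] * 10, pos, ["A"] * 10, ["G"] * 10,
                                 anc=["A"] * 10)


def random_matrix(rng, n_sites, n_ind, p=0.4):
    alleles = (rng.random((n_sites, 2 * n_ind)) < p).astype(np.int8)
    return HaplotypeMatrix(alleles, [f"S{i}" for i in range(n_ind)])


@pytest.fixture
def uniform_map():
    return GeneticMap.uniform({"1": 10_000_000}, rate_cm_per_mb=1.0)
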