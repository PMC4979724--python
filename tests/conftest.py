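import numpy as np
import pytest

from clinezone import GenotypeMatrix


def make_matrix(calls_by_pop, loci=None, era="recent"):
    """Build a GenotypeMatrix from {pop: [[(a, b), ...], ...]} literals."""
    ids, sites, pops, rows = [], [], [], []
    n_loci = None
    for pop, individuals in calls_by_pop.items():
        for i, ind in enumerate(individuals):
            ids.append(f"{pop}_{i + 1}")
            sites.append(pop)
            pops.append(pop)
            rows.append(np.asarray(ind, dtype=np.int64))
            n_loci = len(ind)
    loci = loci or [f"L{k + 1}" for k in range(n_loci)]
    return GenotypeMatrix(
        individual_id=ids, collection_site=sites, population_id=pops,
        era=[era] * len(ids), loci=loci, calls=np.stack(rows),
    )


@pytest.fixture
def two_pop_matrix():
    """Two small populations at two loci with one missing call."""
    return make_matrix(
        {
            "P1": [[(1, 1), (2, 4)], [(1, 3), (2, 2)], [(3, 3), (0, 0)]],
            "P2": [[(1, 3), (4, 4)], [(3, 3), (2, 4)]],
        }
    )


@pytest.fixture(scope="session")
def simulated_zone():
    """One historical-design synthetic dataset shared across tests."""
    from clinezone import (
        SimulationConfig,
        simulate_hybrid_zone,
        simulate_parental_frequencies,
    )

    cfg = SimulationConfig(seed=7)
    pf = simulate_parental_frequencies(cfg)
    gm, metas, truth = simulate_hybrid_zone(cfg, pf)
    return cfg, pf, gm, metas, truth
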