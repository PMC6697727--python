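import dataclasses

import numpy as np
import pytest

from ttwsurrogate import (
    COARSE,
    FINE,
    CommuterNetwork,
    SyntheticScenario,
    ZoneHierarchy,
    generate_products,
)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A reduced synthetic census for fast unit tests (~15k commuters)."""
    return dataclasses.replace(
        SyntheticScenario(),
        n_coarse=12,
        origins_per_coarse=6,
        dest_min=2,
        dest_max=8,
        mean_workers=200.0,
    )


@pytest.fixture(scope="session")
def small_products(small_scenario):
    """(truth, release) pair from the reduced scenario, shared across tests."""
    return generate_products(small_scenario, seed=42)


@pytest.fixture
def toy_hierarchy() -> ZoneHierarchy:
    return ZoneHierarchy(
        origin_parent={"a1": "A", "a2": "A", "b1": "B"},
        dest_parent={"d1": "D", "d2": "D", "e1": "E"},
    )


def random_network(rng: np.random.Generator, n_origins=8, n_dests=8, p=0.4,
                   w_max=50, levels=(COARSE, COARSE)) -> CommuterNetwork:
    origins = [f"o{i}" for i in range(n_origins)]
    dests = [f"d{j}" for j in range(n_dests)]
    edges = {}
    for o in origins:
        for d in dests:
            if rng.random() < p:
                edges[(o, d)] = int(rng.integers(1, w_max))
    if not edges:  # ensure non-degenerate instance
        edges[(origins[0], dests[0])] = 1
    return CommuterNetwork(levels[0], levels[1], edges)
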