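import numpy as np
import pytest

import stsurv
from stsurv import AreaGraph, CountPanel, McmcConfig, ScenarioConfig


@pytest.fixture(scope="session")
def lattice33():
    return stsurv.build_lattice_graph(3, 3)


@pytest.fixture(scope="session")
def planar30():
    return stsurv.build_random_planar_graph(30, seed=42)


@pytest.fixture(scope="session")
def small_panel(planar30):
    """30-area x 8-time null panel (no signals), counts around E=50."""
    cfg = ScenarioConfig(
        n_areas=30, n_times=8, n_unusual=0, signal_magnitude=0.0,
        up_times=frozenset(), down_times=frozenset(),
        expected_range=(50.0, 50.0),
    )
    panel, truth, graph = stsurv.make_scenario(cfg, seed=5, graph=planar30)
    return panel


@pytest.fixture(scope="session")
def quick_cfg():
    """Short but usable chain settings for sampler unit tests."""
    return McmcConfig(n_iterations=800, burn_in=400, thin=4, n_chains=1, seed=0)


def random_graph(rng, n):
    """Erdos-Renyi-ish helper for property tests over arbitrary graphs."""
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < 0.3:
                edges.add((i, j))
    return AreaGraph.from_edges(n, edges)
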