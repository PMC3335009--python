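import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from starpanel.spatial_graph import AdjacencyGraph
from starpanel.star_model import ModelSpec, apply_constraints
from starpanel.synthetic_data import (
    default_true_parameters,
    make_lattice_graph,
    simulate_panel,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def path_graph3() -> AdjacencyGraph:
    """Three counties in a line: A - B - C."""
    return AdjacencyGraph.from_edges(["A", "B", "C"], [(0, 1), (1, 2)])


@pytest.fixture
def lattice_graph() -> AdjacencyGraph:
    """6x6 rook lattice in 2 disconnected bands with a couple of islands."""
    return make_lattice_graph(6, 6, n_components=2, island_fraction=0.05, seed=1)


@pytest.fixture(scope="session")
def vcm_panel():
    """A simulated study-like VCM panel on a 6x6 two-component lattice."""
    graph = make_lattice_graph(6, 6, n_components=2, island_fraction=0.05, seed=7)
    true = default_true_parameters(T=21, seed=7)
    panel, truth = simulate_panel(graph, true)
    return graph, true, panel, truth


def make_toy_spec(y: np.ndarray, blocks=(), hyper=(0.001, 0.001)) -> ModelSpec:
    """Minimal sampler-ready spec around a response vector."""
    spec = ModelSpec(
        kind="toy",
        y=np.asarray(y, dtype=float),
        blocks=tuple(blocks),
        hyper_a=hyper[0],
        hyper_b=hyper[1],
        county_ids=(),
        years=(),
    )
    return apply_constraints(spec)
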