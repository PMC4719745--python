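import random

import pytest
from hypothesis import HealthCheck, settings

from dysmod import LFRParameters, ScoredNetwork, ScoreSimulationParameters, make_benchmark

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def path3():
    """Path graph a-b-c."""
    return ScoredNetwork([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return ScoredNetwork([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def bridged_triangles():
    """Two triangles abc / def joined through a bridge node x.

    The induced subgraph on {a,b,c} | {d,e,f} is exactly two disjoint
    triangles (the bridge node is excluded), while the host stays connected.
    """
    edges = [
        ("a", "b"), ("b", "c"), ("a", "c"),
        ("d", "e"), ("e", "f"), ("d", "f"),
        ("a", "x"), ("x", "d"),
    ]
    return ScoredNetwork(edges)


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by one edge; clique {a,b,c,d} scores z=3 in both conditions."""
    left = ["a", "b", "c", "d"]
    right = ["e", "f", "g", "h"]
    edges = [(u, v) for i, u in enumerate(left) for v in left[i + 1:]]
    edges += [(u, v) for i, u in enumerate(right) for v in right[i + 1:]]
    edges.append(("d", "e"))
    z = {v: 3.0 for v in left}
    return ScoredNetwork(edges, z, dict(z))


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted benchmark shared by operator-level tests."""
    return make_benchmark(
        LFRParameters(n_nodes=150, avg_degree=6, mixing=0.1, seed=123),
        ScoreSimulationParameters(sigma=0.1, seed=123),
        mode="overlap",
    )


@pytest.fixture(scope="session")
def lfr_net(small_benchmark):
    return small_benchmark.network


@pytest.fixture
def rng():
    return random.Random(42)
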