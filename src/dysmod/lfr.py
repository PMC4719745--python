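"""Synthetic community-structured benchmarks with planted expression signals.

Networks follow the Lancichinetti-Fortunato-Radicchi (LFR) construction:
power-law degree and community-size distributions, with a mixing parameter
giving the fraction of each node's edges that leave its community. (The
mixing parameter is exposed here as ``mixing``; it is LFR's mu, called gamma
in some of the module-detection literature.)

On top of the topology, one community (or two, in disjoint mode) is planted
as differentially expressed: its nodes draw z-scores from ``+/-N(mu1, sigma)``
with a random sign, all other nodes from ``N(mu2, sigma)``. The defaults
``n_nodes=300, mu1=3, mu2=0`` emulate interaction networks of a few hundred
genes in which differential expression is strong relative to background
noise; average degrees of 4-10 bracket the sparsity of curated interactome
subnetworks.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from statistics import mean
from typing import Iterator

import networkx as nx
import numpy as np

from .network import ScoredNetwork, is_connected_subset

logger = logging.getLogger(__name__)

__all__ = [
    "LFRParameters",
    "ScoreSimulationParameters",
    "PlantedBenchmark",
    "generate_lfr",
    "select_planted_communities",
    "simulate_zscores",
    "make_benchmark",
    "benchmark_suite",
]


@dataclass(frozen=True)
class LFRParameters:
    """Topology parameters of the synthetic generator.

    ``degree_exponent`` (tau1) and ``community_exponent`` (tau2) default to
    the canonical benchmark settings 2 and 1.5; community sizes span 10-50
    so that planted modules are comparable to the subnetwork sizes the
    optimiser targets. ``max_degree`` defaults to ``n_nodes // 10``.
    """

    n_nodes: int = 300
    avg_degree: float = 4.0
    mixing: float = 0.1
    degree_exponent: float = 2.0
    community_exponent: float = 1.5
    max_degree: int | None = None
    community_size_range: tuple[int, int] = (10, 50)
    seed: int = 0
    max_attempts: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing < 1.0:
            raise ValueError("mixing must lie in (0, 1)")
        if self.degree_exponent <= 1.0 or self.community_exponent <= 1.0:
            raise ValueError("power-law exponents must exceed 1")
        if self.avg_degree >= self.n_nodes:
            raise ValueError("average degree must be below the node count")

    @property
    def effective_max_degree(self) -> int:
        if self.max_degree is not None:
            return self.max_degree
        # n/10 by default, floored so a power-law mean of avg_degree stays feasible
        return max(self.n_nodes // 10, math.ceil(3 * self.avg_degree))


@dataclass(frozen=True)
class ScoreSimulationParameters:
    """Score-simulation parameters: signal mean mu1, background mean mu2, noise sigma."""

    mu1: float = 3.0
    mu2: float = 0.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class PlantedBenchmark:
    """A synthetic network with ground-truth differentially expressed communities.

    ``planted1``/``planted2`` are id sets of the communities that carry the
    expression signal under conditions 1 and 2; in overlap mode they are the
    same community, in disjoint mode two distinct ones.
    """

    network: ScoredNetwork
    community_of: dict[int, int]
    planted1: frozenset[int]
    planted2: frozenset[int]
    mode: str
    lfr_params: LFRParameters | None = None
    score_params: ScoreSimulationParameters | None = None

    def communities(self) -> dict[int, frozenset[int]]:
        out: dict[int, set[int]] = {}
        for node, c in self.community_of.items():
            out.setdefault(c, set()).add(node)
        return {c: frozenset(s) for c, s in out.items()}

    def truth_partition(self) -> list[frozenset[int]]:
        """Ground-truth partition for NMI: planted set(s) versus background."""
        universe = frozenset(range(self.network.n_nodes))
        if self.mode == "overlap":
            groups = [self.planted1, universe - self.planted1]
        else:
            groups = [self.planted1, self.planted2, universe - self.planted1 - self.planted2]
        return [g for g in groups if g]


def generate_lfr(params: LFRParameters, rng: random.Random | None = None) -> tuple[ScoredNetwork, dict[int, int]]:
    """Generate one LFR-style network; returns (network, node id -> community id).

    The generator is retried with fresh sub-seeds until the graph is a single
    connected component; if ``max_attempts`` regenerations all fail, the
    largest connected component of the last attempt is extracted instead
    (logged), which preserves the degree distribution at the cost of a few
    percent of nodes. Z-scores are initialised to zero.
    """
    rng = random.Random(params.seed) if rng is None else rng
    cmin, cmax = params.community_size_range
    g = None
    best_lcc_size = -1
    last_error: Exception | None = None
    for attempt in range(params.max_attempts):
        sub_seed = rng.randrange(2**31)
        try:
            cand = nx.LFR_benchmark_graph(
                params.n_nodes,
                params.degree_exponent,
                params.community_exponent,
                params.mixing,
                average_degree=params.avg_degree,
                max_degree=params.effective_max_degree,
                min_community=cmin,
                max_community=cmax,
                seed=sub_seed,
            )
        except nx.ExceededMaxIterations as exc:  # infeasible draw; retry
            last_error = exc
            continue
        cand.remove_edges_from(nx.selfloop_edges(cand))
        if nx.is_connected(cand):
            g = cand
            break
        lcc_size = max(len(c) for c in nx.connected_components(cand))
        if lcc_size > best_lcc_size:  # keep the draw closest to fully connected
            best_lcc_size = lcc_size
            g = cand
    else:
        if g is None:
            raise ValueError(
                f"LFR generation failed after {params.max_attempts} attempts: {last_error}"
            )
        logger.info(
            "no fully connected draw in %d attempts; extracting largest component "
            "(%d of %d nodes)",
            params.max_attempts, best_lcc_size, params.n_nodes,
        )

    # Use zero-padded labels so sorted label order matches node order.
    width = len(str(params.n_nodes - 1))
    labels = {v: f"g{v:0{width}d}" for v in g.nodes}
    net = ScoredNetwork((labels[u], labels[v]) for u, v in g.edges)
    comm_sets = {frozenset(g.nodes[v]["community"]) for v in g.nodes}
    comm_id = {c: i for i, c in enumerate(sorted(comm_sets, key=lambda c: (len(c), sorted(c))))}
    community_of: dict[int, int] = {}
    for v in g.nodes:
        lab = labels[v]
        if lab in net._index:  # node survived the LCC restriction
            community_of[net._index[lab]] = comm_id[frozenset(g.nodes[v]["community"])]
    return net, community_of


def select_planted_communities(
    community_of: dict[int, int], mode: str, rng: random.Random | None = None
) -> tuple[int, int]:
    """Pick the community id(s) to plant as differentially expressed.

    The first community has the largest size that is <= the mean community
    size. In disjoint mode the second has the closest strictly larger size;
    in overlap mode it is the same community. Ties among equal-size
    communities are broken uniformly at random.
    """
    rng = random.Random(0) if rng is None else rng
    sizes: dict[int, int] = {}
    for c in community_of.values():
        sizes[c] = sizes.get(c, 0) + 1
    if len(sizes) < 2:
        raise ValueError("need at least two communities")
    avg = mean(sizes.values())
    eligible = [s for s in sizes.values() if s <= avg]
    s_c1 = max(eligible)
    cands1 = sorted(c for c, s in sizes.items() if s == s_c1)
    c1 = cands1[rng.randrange(len(cands1))]
    if mode == "overlap":
        return c1, c1
    bigger = [s for s in sizes.values() if s > s_c1]
    if not bigger:
        raise ValueError("no community strictly larger than the first planted size")
    s_c2 = min(bigger)
    cands2 = sorted(c for c, s in sizes.items() if s == s_c2 and c != c1)
    c2 = cands2[rng.randrange(len(cands2))]
    return c1, c2


def simulate_zscores(
    bench: PlantedBenchmark,
    sp: ScoreSimulationParameters,
    rng: np.random.Generator | None = None,
) -> ScoredNetwork:
    """Fill both z-score tracks of the benchmark network.

    Planted nodes draw ``z ~ +/-N(mu1, sigma)`` with a per-node random sign;
    all other nodes draw ``z ~ N(mu2, sigma)``.
    """
    rng = np.random.default_rng(sp.seed) if rng is None else rng
    net = bench.network
    n = net.n_nodes
    tracks = []
    for planted in (bench.planted1, bench.planted2):
        z = rng.normal(sp.mu2, sp.sigma, n)
        idx = np.array(sorted(planted), dtype=int)
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        z[idx] = signs * rng.normal(sp.mu1, sp.sigma, len(idx))
        tracks.append(z)
    net.set_scores(tracks[0], tracks[1])
    return net


def make_benchmark(
    lfr_params: LFRParameters,
    score_params: ScoreSimulationParameters,
    mode: str = "overlap",
    rng: random.Random | None = None,
) -> PlantedBenchmark:
    """Generate topology, plant communities and simulate scores in one call.

    A benchmark is well-posed only if the planted communities induce
    connected subgraphs — otherwise the ground truth is not a valid
    subnetwork and no connected-module method could ever recover it exactly.
    Draws violating this are discarded and the topology regenerated (bounded
    retries; the last draw is kept with a warning if all fail).
    """
    rng = random.Random(lfr_params.seed) if rng is None else rng
    for attempt in range(20):
        net, community_of = generate_lfr(lfr_params, rng)
        c1, c2 = select_planted_communities(community_of, mode, rng)
        planted1 = frozenset(v for v, c in community_of.items() if c == c1)
        planted2 = frozenset(v for v, c in community_of.items() if c == c2)
        ok = is_connected_subset(net, planted1)
        if mode == "disjoint":
            ok = ok and is_connected_subset(net, planted2)
        if ok:
            break
    else:
        logger.warning("planted community disconnected in all draws; keeping last")
    bench = PlantedBenchmark(
        network=net,
        community_of=community_of,
        planted1=planted1,
        planted2=planted2,
        mode=mode,
        lfr_params=lfr_params,
        score_params=score_params,
    )
    np_rng = np.random.default_rng(rng.randrange(2**31))
    simulate_zscores(bench, score_params, np_rng)
    return bench


def benchmark_suite(
    mode: str = "overlap",
    mixings: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    sigmas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    degrees: tuple[float, ...] = (4, 6, 8, 10),
    base_mixing: float = 0.1,
    base_sigma: float = 0.1,
    seed: int = 0,
    n_nodes: int = 300,
) -> Iterator[PlantedBenchmark]:
    """The standard perturbation sweep.

    One parameter is varied while the other stays at 0.1: the settings are
    ``{(mixing, 0.1)} U {(0.1, sigma)}`` (the shared point counted once),
    each crossed with every average degree. The default grid yields
    9 x 4 = 36 benchmarks per mode, all reproducible from ``seed``.
    """
    settings: list[tuple[float, float]] = []
    for m in mixings:
        settings.append((m, base_sigma))
    for s in sigmas:
        if (base_mixing, s) not in settings:
            settings.append((base_mixing, s))
    master = random.Random(seed)
    for mixing, sigma in settings:
        for k in degrees:
            sub_seed = master.randrange(2**31)
            lfr = LFRParameters(n_nodes=n_nodes, avg_degree=float(k), mixing=mixing, seed=sub_seed)
            sp = ScoreSimulationParameters(sigma=sigma, seed=sub_seed)
            yield make_benchmark(lfr, sp, mode=mode, rng=random.Random(sub_seed))
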