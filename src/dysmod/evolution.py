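"""Generational evolutionary optimiser over connected subnetworks.

Every operator preserves the defining invariants of an individual: each of
its node sets induces a connected subgraph of fixed size, and in disjoint
mode the two sets never overlap. Connectivity is maintained the cheap way —
removal candidates are vetted with a depth-first search over the remaining
set, and replacement nodes are always host-graph neighbours of a surviving
node, so insertion can never disconnect the set.

Generation schedule: evaluate -> elitist copy of the two best individuals ->
binary tournament selection of a parent pool -> crossover on consecutive
parent pairs -> mutation -> next generation. All randomness flows from a
single ``random.Random`` instance, so runs are reproducible bit-for-bit from
the seed.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .fitness import FitnessValue, evaluate
from .network import Individual, ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EAParameters",
    "RunResult",
    "sample_connected_subnetwork",
    "initialise_population",
    "mutate",
    "crossover",
    "tournament_select",
    "evolve",
    "run_size_sweep",
]

_INIT_RETRIES = 200


@dataclass(frozen=True)
class EAParameters:
    """Optimiser configuration.

    Defaults follow the reference protocol used throughout: 100 generations,
    population 200, crossover rate 0.1, mutation rate 0.9. In disjoint mode
    ``subnetwork_size2`` sets the size of the second (condition-2) module;
    it defaults to ``subnetwork_size``.
    """

    generations: int = 100
    population_size: int = 200
    crossover_rate: float = 0.1
    mutation_rate: float = 0.9
    subnetwork_size: int = 10
    subnetwork_size2: int | None = None
    mode: str = "overlap"
    seed: int = 0
    mutation_max_tries: int = 50
    tournament_size: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("overlap", "disjoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.crossover_rate <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("operator rates must lie in [0, 1]")
        if self.subnetwork_size < 2:
            raise ValueError("subnetwork size must be at least 2")
        if self.population_size < 2 or self.generations < 0:
            raise ValueError("population_size >= 2 and generations >= 0 required")

    @property
    def size1(self) -> int:
        return self.subnetwork_size

    @property
    def size2(self) -> int:
        return self.subnetwork_size2 if self.subnetwork_size2 is not None else self.subnetwork_size


@dataclass
class RunResult:
    """Outcome of one optimisation run."""

    best: Individual
    best_fitness: FitnessValue
    history: list[float]
    population_final: list[Individual]
    seed: int
    params: EAParameters = field(repr=False, default=None)

    def to_dict(self, net: ScoredNetwork) -> dict:
        return {
            "mode": self.best.mode,
            "seed": self.seed,
            "size1": len(self.best.s1),
            "size2": len(self.best.s2),
            "best_s1": net.labels_of(self.best.s1),
            "best_s2": net.labels_of(self.best.s2),
            "fitness": self.best_fitness.to_dict(),
            "history": self.history,
        }


def sample_connected_subnetwork(
    net: ScoredNetwork,
    size: int,
    rng: random.Random,
    allowed: frozenset[int] | None = None,
    start: int | None = None,
) -> frozenset[int]:
    """Sample a connected node set of exactly ``size`` nodes by randomised DFS.

    A start node is drawn uniformly (within ``allowed`` when given) and a
    depth-first search expands to uniformly chosen unvisited neighbours until
    the target size is reached. On a connected search space the target size
    is always reachable.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    n_avail = net.n_nodes if allowed is None else len(allowed)
    if size > n_avail:
        raise ValueError(f"requested size {size} exceeds {n_avail} available nodes")
    if start is None:
        start = rng.randrange(net.n_nodes) if allowed is None else rng.choice(sorted(allowed))
    visited = {start}
    stack = [start]
    nbrs = net.nbrs
    while stack and len(visited) < size:
        v = stack[-1]
        if allowed is None:
            cand = [w for w in nbrs[v] if w not in visited]
        else:
            cand = [w for w in nbrs[v] if w not in visited and w in allowed]
        if not cand:
            stack.pop()
            continue
        w = cand[rng.randrange(len(cand))]
        visited.add(w)
        stack.append(w)
    if len(visited) < size:
        raise ValueError("search space disconnected: target size unreachable")
    return frozenset(visited)


def _sample_disjoint_pair(
    net: ScoredNetwork, size1: int, size2: int, rng: random.Random
) -> Individual:
    for _ in range(_INIT_RETRIES):
        s1 = sample_connected_subnetwork(net, size1, rng)
        for _ in range(10):
            s2 = sample_connected_subnetwork(net, size2, rng)
            if not (s1 & s2):
                return Individual.from_sets(s1, s2)
    raise ValueError(
        "could not sample two disjoint connected sets of sizes "
        f"{size1}+{size2} on a {net.n_nodes}-node graph"
    )


def initialise_population(
    net: ScoredNetwork, params: EAParameters, rng: random.Random
) -> list[Individual]:
    """Random population of valid individuals (DFS-grown connected sets)."""
    if params.mode == "disjoint" and params.size1 + params.size2 > net.n_nodes:
        raise ValueError("disjoint mode needs size1 + size2 <= number of nodes")
    pop: list[Individual] = []
    for _ in range(params.population_size):
        if params.mode == "overlap":
            pop.append(Individual.from_set(sample_connected_subnetwork(net, params.size1, rng)))
        else:
            pop.append(_sample_disjoint_pair(net, params.size1, params.size2, rng))
    return pop


def _connected_ids(net: ScoredNetwork, ids: frozenset[int]) -> bool:
    # internal fast path: ids assumed valid and nonempty
    start = next(iter(ids))
    seen = {start}
    stack = [start]
    adj = net.adj
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w in ids and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(ids)


def _mutate_set(
    net: ScoredNetwork,
    s: frozenset[int],
    forbidden: frozenset[int],
    max_tries: int,
    rng: random.Random,
) -> frozenset[int] | None:
    """One remove-and-replace move on a connected set, or None if inadmissible.

    A random member whose removal keeps the remainder connected is replaced
    by a host-graph neighbour of a random surviving node (new node not in the
    set and not in ``forbidden``); adding a neighbour of a surviving node
    cannot disconnect the remainder.
    """
    members = sorted(s)
    nbrs = net.nbrs
    for _ in range(max_tries):
        v = members[rng.randrange(len(members))]
        rem = s - {v}
        if not rem or not _connected_ids(net, rem):
            continue
        rem_sorted = sorted(rem)
        anchor = rem_sorted[rng.randrange(len(rem_sorted))]
        cand = [w for w in nbrs[anchor] if w not in s and w not in forbidden]
        if not cand:
            continue
        w = cand[rng.randrange(len(cand))]
        return rem | {w}
    return None


def mutate(
    net: ScoredNetwork, ind: Individual, params: EAParameters, rng: random.Random
) -> Individual:
    """Connectivity-preserving point mutation.

    With probability ``mutation_rate`` one node is swapped out of each node
    set (both sets independently in disjoint mode). If no admissible move is
    found within ``mutation_max_tries`` picks, the set is left unchanged.
    """
    if rng.random() >= params.mutation_rate:
        return ind
    tries = params.mutation_max_tries
    if ind.mode == "overlap":
        new = _mutate_set(net, ind.s1, frozenset(), tries, rng)
        return ind if new is None else Individual.from_set(new)
    new1 = _mutate_set(net, ind.s1, ind.s2, tries, rng)
    s1 = ind.s1 if new1 is None else frozenset(new1)
    new2 = _mutate_set(net, ind.s2, s1, tries, rng)
    s2 = ind.s2 if new2 is None else frozenset(new2)
    if new1 is None and new2 is None:
        return ind
    return Individual.from_sets(s1, s2)


def _regrow_pair(
    net: ScoredNetwork, merged: frozenset[int], size_a: int, size_b: int, rng: random.Random
) -> tuple[frozenset[int], frozenset[int]]:
    start_a = rng.choice(sorted(merged))
    start_b = rng.choice(sorted(merged))
    child_a = sample_connected_subnetwork(net, size_a, rng, allowed=merged, start=start_a)
    child_b = sample_connected_subnetwork(net, size_b, rng, allowed=merged, start=start_b)
    return child_a, child_b


def crossover(
    net: ScoredNetwork,
    p1: Individual,
    p2: Individual,
    params: EAParameters,
    rng: random.Random,
) -> tuple[Individual, Individual]:
    """Merge-and-resample crossover.

    Active with probability ``crossover_rate`` and only when the parents'
    corresponding node sets intersect (their union is then connected): the
    two parent sets are merged and two children are regrown inside the merged
    set by randomised DFS from random start nodes, preserving the per-set
    sizes. Parents that share no node are returned unchanged.
    """
    if p1.mode != p2.mode:
        raise ValueError("parents must share a mode")
    if rng.random() >= params.crossover_rate:
        return p1, p2
    if p1.mode == "overlap":
        if not (p1.s1 & p2.s1):
            return p1, p2
        merged = p1.s1 | p2.s1
        c1, c2 = _regrow_pair(net, merged, len(p1.s1), len(p2.s1), rng)
        return Individual.from_set(c1), Individual.from_set(c2)

    merged1 = p1.s1 | p2.s1 if p1.s1 & p2.s1 else None
    merged2 = p1.s2 | p2.s2 if p1.s2 & p2.s2 else None
    if merged1 is None and merged2 is None:
        return p1, p2
    for _ in range(10):
        if merged1 is not None:
            c1a, c1b = _regrow_pair(net, merged1, len(p1.s1), len(p2.s1), rng)
        else:
            c1a, c1b = p1.s1, p2.s1
        if merged2 is not None:
            c2a, c2b = _regrow_pair(net, merged2, len(p1.s2), len(p2.s2), rng)
        else:
            c2a, c2b = p1.s2, p2.s2
        if not (c1a & c2a) and not (c1b & c2b):
            return Individual.from_sets(c1a, c2a), Individual.from_sets(c1b, c2b)
    return p1, p2


def tournament_select(
    population: Sequence[Individual],
    fitnesses: Sequence[FitnessValue],
    params: EAParameters,
    rng: random.Random,
) -> list[Individual]:
    """Binary (by default) tournaments on F_bar; lower wins, ties random."""
    if not population or len(population) != len(fitnesses):
        raise ValueError("population and fitnesses must be nonempty and aligned")
    n = len(population)
    k = params.tournament_size
    pool: list[Individual] = []
    for _ in range(params.population_size):
        contenders = [rng.randrange(n) for _ in range(k)]
        best_f = min(fitnesses[i].F_bar for i in contenders)
        winners = [i for i in contenders if fitnesses[i].F_bar == best_f]
        pool.append(population[winners[rng.randrange(len(winners))]])
    return pool


def evolve(
    net: ScoredNetwork, params: EAParameters, rng: random.Random | None = None
) -> RunResult:
    """Run the full generational loop and return the best-ever individual.

    ``history`` records the best F_bar seen in each evaluated population
    (``generations + 1`` entries); with elitism it is non-increasing.
    """
    rng = random.Random(params.seed) if rng is None else rng
    pop = initialise_population(net, params, rng)
    cache: dict = {}

    def fit(ind: Individual) -> FitnessValue:
        key = ind.key()
        fv = cache.get(key)
        if fv is None:
            fv = evaluate(net, ind)
            cache[key] = fv
        return fv

    best_ind: Individual | None = None
    best_fv: FitnessValue | None = None
    history: list[float] = []

    for gen in range(params.generations + 1):
        fits = [fit(ind) for ind in pop]
        gen_best = min(range(len(pop)), key=lambda i: fits[i].F_bar)
        if best_fv is None or fits[gen_best].F_bar < best_fv.F_bar:
            best_ind, best_fv = pop[gen_best], fits[gen_best]
        history.append(best_fv.F_bar)
        if gen % 20 == 0:
            mean_f = sum(f.F_bar for f in fits) / len(fits)
            logger.info("gen %d: best F_bar=%.6f mean F_bar=%.6f", gen, best_fv.F_bar, mean_f)
        if gen == params.generations:
            break

        order = sorted(range(len(pop)), key=lambda i: fits[i].F_bar)
        elites = [pop[order[0]], pop[order[1]]]
        parents = tournament_select(pop, fits, params, rng)
        offspring: list[Individual] = []
        for i in range(0, len(parents) - 1, 2):
            c1, c2 = crossover(net, parents[i], parents[i + 1], params, rng)
            offspring.append(c1)
            offspring.append(c2)
        if len(parents) % 2:
            offspring.append(parents[-1])
        offspring = [mutate(net, ind, params, rng) for ind in offspring]
        pop = elites + offspring[: params.population_size - 2]

    return RunResult(
        best=best_ind,
        best_fitness=best_fv,
        history=history,
        population_final=pop,
        seed=params.seed,
        params=params,
    )


def run_size_sweep(
    net: ScoredNetwork,
    sizes: Iterable[int],
    runs_per_size: int,
    params: EAParameters,
    rng: random.Random | None = None,
) -> list[RunResult]:
    """Independent seeded runs for every (size, replicate) combination."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    rng = random.Random(params.seed) if rng is None else rng
    results: list[RunResult] = []
    for size in sizes:
        for _ in range(runs_per_size):
            run_seed = rng.randrange(2**31)
            run_params = replace(params, subnetwork_size=size, subnetwork_size2=None, seed=run_seed)
            results.append(evolve(net, run_params))
    return results
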