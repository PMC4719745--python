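"""Fitness functions of the module-detection optimiser.

The quality of a candidate module combines differential expression with
local topology:

* the subnetwork z-score ``z_N = (1/sqrt(|N|)) * sum_i |z_i|`` aggregates
  per-node differential-expression z-scores over the node set ``N``;
* in *overlap* mode (one module, two conditions) the topological reward is
  the average clustering coefficient of the induced subgraph;
* in *disjoint* mode (one module per condition) the reward is the Newman
  two-module modularity ``Q`` of the induced union subgraph, with the
  standard within-module restriction of the double sum and the
  configuration-model null ``R_ij = k_i k_j / 2E``.

The raw fitness ``F = z(S1) + z(S2) + topo`` is maximised by minimising
``F_bar = 1 / (1 + F)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from typing import Iterable

from .network import Individual, ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessValue",
    "subnetwork_zscore",
    "average_clustering",
    "modularity_two_modules",
    "evaluate",
]


@dataclass(frozen=True)
class FitnessValue:
    """All components of one fitness evaluation.

    ``topo`` is the average clustering coefficient in overlap mode (in
    ``[0, 1]``) and the two-module modularity in disjoint mode (in
    ``[-1, 1]``). ``F_bar = 1/(1+F)`` is the quantity the optimiser
    minimises; lower is better.
    """

    z_s1: float
    z_s2: float
    topo: float
    F: float
    F_bar: float

    def to_dict(self) -> dict:
        return asdict(self)


def subnetwork_zscore(net: ScoredNetwork, nodes: Iterable, condition: int) -> float:
    """Aggregate z-score of a node set: ``sum(|z_i|) / sqrt(|N|)``.

    Always non-negative; absolute values make it insensitive to the
    direction of regulation.
    """
    ids = net.as_ids(nodes)
    if not ids:
        raise ValueError("subnetwork z-score of the empty set is undefined")
    absz = net.abs_z(condition)
    return sum(absz[i] for i in ids) / math.sqrt(len(ids))


def average_clustering(net: ScoredNetwork, nodes: Iterable) -> float:
    """Average local clustering coefficient of the induced subgraph.

    For each node, the fraction of its induced-neighbour pairs that are
    themselves connected; nodes of induced degree < 2 contribute 0.
    """
    ids = net.as_ids(nodes)
    if not ids:
        raise ValueError("clustering of the empty set is undefined")
    adj = net.adj
    total = 0.0
    for v in ids:
        nb = adj[v] & ids
        d = len(nb)
        if d < 2:
            continue
        links = sum(len(adj[u] & nb) for u in nb) // 2
        total += 2.0 * links / (d * (d - 1))
    return total / len(ids)


def modularity_two_modules(net: ScoredNetwork, s1: Iterable, s2: Iterable) -> float:
    """Newman modularity of the two-module partition of the induced union.

    Evaluated on the subgraph induced by ``s1 | s2`` (its adjacency, degrees
    and edge count), summing ``A_ij - k_i k_j / 2E`` over node pairs that
    share a module and dividing by ``2E``. Without the same-module
    restriction the sum is identically zero, so the restriction is part of
    the definition. An edgeless induced union is degenerate: Q := 0.
    """
    m1 = net.as_ids(s1)
    m2 = net.as_ids(s2)
    if not m1 or not m2:
        raise ValueError("both modules must be nonempty")
    if m1 & m2:
        raise ValueError("modules must be disjoint")
    union = m1 | m2
    adj = net.adj
    deg = {v: len(adj[v] & union) for v in union}
    two_e = sum(deg.values())
    if two_e == 0:
        logger.warning("induced union subgraph has no edges; Q defined as 0")
        return 0.0
    q = 0.0
    for module in (m1, m2):
        a_sum = sum(len(adj[v] & module) for v in module)  # ordered pairs
        k_sum = sum(deg[v] for v in module)
        q += a_sum - k_sum * k_sum / two_e
    return q / two_e


def evaluate(net: ScoredNetwork, ind: Individual) -> FitnessValue:
    """Evaluate an individual, returning all fitness components."""
    if ind.mode == "overlap":
        z1 = subnetwork_zscore(net, ind.s1, 1)
        z2 = subnetwork_zscore(net, ind.s1, 2)
        topo = average_clustering(net, ind.s1)
    elif ind.mode == "disjoint":
        z1 = subnetwork_zscore(net, ind.s1, 1)
        z2 = subnetwork_zscore(net, ind.s2, 2)
        topo = modularity_two_modules(net, ind.s1, ind.s2)
    else:
        raise ValueError(f"unknown mode {ind.mode!r}")
    f = abs(z1) + abs(z2) + topo
    return FitnessValue(z_s1=z1, z_s2=z2, topo=topo, F=f, F_bar=1.0 / (1.0 + f))
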