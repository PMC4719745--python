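"""Consensus over repeated optimisation runs across subnetwork sizes.

Each run contributes its best individual; the identification frequency of a
node is the fraction of runs whose best solution contains it (all sizes
pooled). Nodes above a strict frequency threshold form the consensus set,
whose largest connected component is the reported consensus module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .evolution import RunResult
from .network import ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "node_frequency", "node_frequency_by_size", "consensus_subnetwork"]


@dataclass
class ConsensusResult:
    frequency: dict[int, float]
    threshold: float
    consensus_nodes: frozenset[int]
    consensus_lcc: frozenset[int]

    def to_rows(self, net: ScoredNetwork) -> list[dict]:
        rows = []
        for node in sorted(self.frequency, key=lambda v: (-self.frequency[v], net.labels[v])):
            rows.append(
                {
                    "node": net.labels[node],
                    "frequency": self.frequency[node],
                    "in_consensus": node in self.consensus_nodes,
                    "in_lcc": node in self.consensus_lcc,
                }
            )
        return rows


def node_frequency(results: Sequence[RunResult], component: str = "s1") -> dict[int, float]:
    """Fraction of runs whose best individual contains each node.

    ``component`` selects which node set of the best individual counts:
    ``s1``, ``s2`` or their ``union``. Nodes never selected are absent
    (implicitly frequency 0).
    """
    if not results:
        raise ValueError("need at least one run result")
    if component not in ("s1", "s2", "union"):
        raise ValueError(f"unknown component {component!r}")
    counts: dict[int, int] = {}
    for res in results:
        best = res.best
        nodes = {"s1": best.s1, "s2": best.s2, "union": best.union}[component]
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
    n = len(results)
    return {v: c / n for v, c in counts.items()}


def node_frequency_by_size(
    results: Sequence[RunResult], component: str = "s1"
) -> dict[int, dict[int, float]]:
    """Identification frequencies computed separately per subnetwork size.

    Pooled frequencies drive the consensus; the per-size breakdown shows
    whether a node is selected consistently or only at particular sizes.
    """
    by_size: dict[int, list[RunResult]] = {}
    for res in results:
        by_size.setdefault(len(res.best.s1), []).append(res)
    return {size: node_frequency(runs, component) for size, runs in sorted(by_size.items())}


def consensus_subnetwork(
    freq: dict[int, float], net: ScoredNetwork, threshold: float = 0.3
) -> ConsensusResult:
    """Nodes with frequency strictly above ``threshold`` and their largest component.

    Component ties are broken by total frequency mass, then by sorted node
    labels, so the result is deterministic.
    """
    consensus = frozenset(v for v, f in freq.items() if f > threshold)
    if not consensus:
        logger.warning("consensus is empty at threshold %g", threshold)
        return ConsensusResult(freq, threshold, frozenset(), frozenset())
    g = nx.Graph()
    g.add_nodes_from(consensus)
    g.add_edges_from((i, j) for i, j in net.edges if i in consensus and j in consensus)
    lcc = max(
        nx.connected_components(g),
        key=lambda c: (len(c), sum(freq[v] for v in c), sorted(net.labels[v] for v in c)),
    )
    return ConsensusResult(freq, threshold, consensus, frozenset(lcc))
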