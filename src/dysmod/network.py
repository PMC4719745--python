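"""Core graph + score container shared by all modules.

A :class:`ScoredNetwork` is an undirected, simple, connected molecular
interaction network in which every node carries two differential-expression
z-scores, one per experimental condition (for instance, one disease subtype
versus control and a second subtype versus control).

Node labels are case-sensitive strings (gene/protein symbols). Internally,
nodes are mapped onto dense integer ids ``0..n-1`` assigned in sorted label
order. All set-valued operations downstream (random subnetwork sampling,
mutation, crossover) work on integer ids: integer hashing is stable across
interpreter sessions, so seeded runs are byte-reproducible, which would not
hold for salted string hashes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ScoredNetwork", "Individual", "load_network", "is_connected_subset"]


class ScoredNetwork:
    """Undirected interaction network with two per-node z-score tracks.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` label pairs. Self-loops and duplicate edges
        are dropped (with a logged count). If the resulting graph has more
        than one connected component, the largest one is kept and a warning
        is logged; every operator downstream assumes a connected host graph.
    z1, z2
        Optional mappings ``label -> z`` for conditions 1 and 2. Nodes
        missing from a mapping receive a z-score of exactly 0 (the
        convention for genes that are not differentially expressed).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        z1: Mapping[str, float] | None = None,
        z2: Mapping[str, float] | None = None,
    ) -> None:
        edge_list = [(str(u), str(v)) for u, v in edges]
        n_self = sum(1 for u, v in edge_list if u == v)
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edge_list if u != v)
        if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
            raise ValueError("network must contain at least one edge")
        n_dup = len(edge_list) - n_self - g.number_of_edges()
        if n_self:
            logger.info("dropped %d self-loop(s)", n_self)
        if n_dup:
            logger.info("dropped %d duplicate edge(s)", n_dup)
        if not nx.is_connected(g):
            lcc = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
            logger.warning(
                "input graph has %d components; keeping largest (%d of %d nodes)",
                nx.number_connected_components(g), len(lcc), g.number_of_nodes(),
            )
            g = g.subgraph(lcc).copy()

        self.labels: tuple[str, ...] = tuple(sorted(g.nodes))
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        adj: list[set[int]] = [set() for _ in range(n)]
        for u, v in g.edges:
            iu, iv = self._index[u], self._index[v]
            adj[iu].add(iv)
            adj[iv].add(iu)
        #: membership-test adjacency (frozensets of int ids)
        self.adj: tuple[frozenset[int], ...] = tuple(frozenset(a) for a in adj)
        #: iteration adjacency in sorted order (deterministic traversal)
        self.nbrs: tuple[tuple[int, ...], ...] = tuple(tuple(sorted(a)) for a in adj)
        z1 = z1 or {}
        z2 = z2 or {}
        self.z1 = np.array([float(z1.get(lab, 0.0)) for lab in self.labels])
        self.z2 = np.array([float(z2.get(lab, 0.0)) for lab in self.labels])
        self._abs_z = {1: np.abs(self.z1), 2: np.abs(self.z2)}

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adj) // 2

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Edges as ordered id pairs ``(i, j)`` with ``i < j``."""
        return [(i, j) for i in range(self.n_nodes) for j in self.nbrs[i] if i < j]

    def abs_z(self, condition: int) -> np.ndarray:
        return self._abs_z[condition]

    def set_scores(self, z1: np.ndarray, z2: np.ndarray) -> None:
        """Replace both score tracks (length-n arrays in id order)."""
        self.z1 = np.asarray(z1, dtype=float).copy()
        self.z2 = np.asarray(z2, dtype=float).copy()
        if self.z1.shape != (self.n_nodes,) or self.z2.shape != (self.n_nodes,):
            raise ValueError("score arrays must have one entry per node")
        self._abs_z = {1: np.abs(self.z1), 2: np.abs(self.z2)}

    # -- label/id translation ---------------------------------------------

    def ids(self, labels: Iterable[str]) -> frozenset[int]:
        return frozenset(self._index[str(lab)] for lab in labels)

    def labels_of(self, ids: Iterable[int]) -> list[str]:
        return sorted(self.labels[i] for i in ids)

    def as_ids(self, nodes: Iterable) -> frozenset[int]:
        """Normalise a node collection (labels or ids) to integer ids."""
        nodes = list(nodes)
        if not nodes:
            return frozenset()
        if isinstance(nodes[0], str):
            return self.ids(nodes)
        out = frozenset(int(v) for v in nodes)
        if out and (min(out) < 0 or max(out) >= self.n_nodes):
            raise ValueError("node id out of range")
        return out

    # -- serialisation -----------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            g.add_node(lab, z1=float(self.z1[i]), z2=float(self.z2[i]))
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in self.edges)
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def to_json(self) -> dict:
        return {
            "nodes": [
                {"id": lab, "z1": float(self.z1[i]), "z2": float(self.z2[i])}
                for i, lab in enumerate(self.labels)
            ],
            "edges": [[self.labels[i], self.labels[j]] for i, j in self.edges],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), sort_keys=True, indent=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScoredNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class Individual:
    """A candidate solution of the optimiser.

    ``overlap`` mode: a single connected node set scored under both
    conditions (``s1 == s2``). ``disjoint`` mode: two disjoint connected
    node sets, ``s1`` scored under condition 1 and ``s2`` under condition 2.
    Node sets hold integer ids of the host :class:`ScoredNetwork`.
    """

    mode: str
    s1: frozenset[int]
    s2: frozenset[int]

    @classmethod
    def from_set(cls, nodes: frozenset[int]) -> "Individual":
        fs = frozenset(nodes)
        return cls("overlap", fs, fs)

    @classmethod
    def from_sets(cls, s1: frozenset[int], s2: frozenset[int]) -> "Individual":
        return cls("disjoint", frozenset(s1), frozenset(s2))

    @property
    def union(self) -> frozenset[int]:
        return self.s1 | self.s2

    def key(self):
        """Hashable identity used for fitness caching."""
        return self.s1 if self.mode == "overlap" else (self.s1, self.s2)

    def validate(self, net: ScoredNetwork, size1: int, size2: int | None = None) -> None:
        if self.mode not in ("overlap", "disjoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "overlap":
            if self.s1 != self.s2:
                raise ValueError("overlap individual must have s1 == s2")
            if len(self.s1) != size1:
                raise ValueError("wrong subnetwork size")
            if not is_connected_subset(net, self.s1):
                raise ValueError("node set is not connected")
        else:
            size2 = size1 if size2 is None else size2
            if len(self.s1) != size1 or len(self.s2) != size2:
                raise ValueError("wrong subnetwork size")
            if self.s1 & self.s2:
                raise ValueError("disjoint individual has overlapping sets")
            if not is_connected_subset(net, self.s1) or not is_connected_subset(net, self.s2):
                raise ValueError("node set is not connected")


def is_connected_subset(net: ScoredNetwork, nodes: Iterable) -> bool:
    """True iff ``nodes`` induces a single connected component in ``net``.

    A singleton set counts as connected. Raises on an empty set.
    """
    ids = net.as_ids(nodes)
    if not ids:
        raise ValueError("connectivity of the empty set is undefined")
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


def load_network(
    edge_list_path: str | Path,
    scores1: Mapping[str, float] | None = None,
    scores2: Mapping[str, float] | None = None,
) -> ScoredNetwork:
    """Load a two-column tab-separated edge list into a :class:`ScoredNetwork`.

    Lines are split on tabs (falling back to any whitespace); a 3-column SIF
    dialect ``node  interaction-type  node`` is accepted by ignoring the
    middle column. Blank lines and ``#`` comments are skipped. Score maps may
    be partial: nodes missing from a map get z = 0.
    """
    path = Path(edge_list_path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) == 3:
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"cannot parse edge line: {line!r}")
    if not edges:
        raise ValueError(f"no edges found in {path}")
    return ScoredNetwork(edges, scores1, scores2)
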