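"""Performance metrics against planted ground truth, and empirical significance.

Two complementary views of recovery quality:

* prediction accuracy ``PA = 1 - (FN + FP) / (TN + TP)`` treats module
  membership as a per-node binary classification over the whole network;
* normalised mutual information compares the *partition* induced by a
  solution (module set(s) plus background) with the planted partition via
  the confusion-matrix form ``-2 sum C_ij log(C_ij N / (C_i. C_.j))``
  divided by ``sum C_i. log(C_i./N) + sum C_.j log(C_.j/N)``, which equals
  ``2 I(O;A) / (H(O) + H(A))``. The log base cancels; natural log is used.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .evolution import sample_connected_subnetwork
from .fitness import subnetwork_zscore
from .network import Individual, ScoredNetwork

__all__ = [
    "ConfusionCounts",
    "prediction_accuracy",
    "normalised_mutual_information",
    "partition_from_individual",
    "subnetwork_significance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(optimised: frozenset, actual: frozenset, universe: frozenset) -> ConfusionCounts:
    if not optimised <= universe or not actual <= universe:
        raise ValueError("both node sets must be subsets of the universe")
    tp = len(optimised & actual)
    fp = len(optimised - actual)
    fn = len(actual - optimised)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def prediction_accuracy(optimised: Iterable, actual: Iterable, universe: Iterable) -> float:
    """``1 - (FN + FP) / (TN + TP)`` over node-wise membership; 1 iff identical."""
    universe = frozenset(universe)
    c = confusion(frozenset(optimised), frozenset(actual), universe)
    if c.tn + c.tp == 0:
        raise ValueError("prediction accuracy undefined when TN + TP = 0")
    return 1.0 - (c.fn + c.fp) / (c.tn + c.tp)


def _as_partition(groups: Sequence[Iterable]) -> list[frozenset]:
    part = [frozenset(g) for g in groups if len(frozenset(g)) > 0]
    n = sum(len(g) for g in part)
    if len(frozenset().union(*part)) != n:
        raise ValueError("groups must be disjoint")
    return part


def normalised_mutual_information(partition_o: Sequence[Iterable], partition_a: Sequence[Iterable]) -> float:
    """Confusion-matrix NMI between two partitions of the same node universe.

    Returns a value in [0, 1]; 1 iff the partitions are identical up to
    relabelling. When both partitions are the trivial single group the
    partitions are identical, so the value is defined as 1.
    """
    po = _as_partition(partition_o)
    pa = _as_partition(partition_a)
    uo = frozenset().union(*po)
    ua = frozenset().union(*pa)
    if uo != ua:
        raise ValueError("partitions must cover the same node universe")
    n = len(uo)
    if len(po) == 1 and len(pa) == 1:
        return 1.0
    numer = 0.0
    for gi in po:
        for gj in pa:
            cij = len(gi & gj)
            if cij:
                numer += cij * math.log(cij * n / (len(gi) * len(gj)))
    numer *= -2.0
    denom = sum(len(g) * math.log(len(g) / n) for g in po)
    denom += sum(len(g) * math.log(len(g) / n) for g in pa)
    if denom == 0.0:
        # both partitions all-singletons: identical up to relabelling
        return 1.0
    return numer / denom


def partition_from_individual(ind: Individual, universe: Iterable) -> list[frozenset]:
    """Partition induced by a solution: module set(s) plus background."""
    universe = frozenset(universe)
    if ind.mode == "overlap":
        groups = [ind.s1, universe - ind.s1]
    else:
        groups = [ind.s1, ind.s2, universe - ind.s1 - ind.s2]
    return [g for g in groups if g]


def subnetwork_significance(
    net: ScoredNetwork,
    nodes: Iterable,
    condition: int,
    n_samples: int = 1000,
    rng: random.Random | None = None,
) -> tuple[float, float]:
    """Empirical significance of a subnetwork z-score.

    The null draws ``n_samples`` random connected subnetworks of the same
    size (randomised DFS from uniform start nodes) and counts how often the
    null z-score reaches the observed one; the add-one-smoothed fraction
    ``(r + 1) / (n + 1)`` is returned alongside the observed z.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = random.Random(0) if rng is None else rng
    ids = net.as_ids(nodes)
    z_obs = subnetwork_zscore(net, ids, condition)
    r = 0
    for _ in range(n_samples):
        sample = sample_connected_subnetwork(net, len(ids), rng)
        if subnetwork_zscore(net, sample, condition) >= z_obs:
            r += 1
    return z_obs, (r + 1) / (n_samples + 1)
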