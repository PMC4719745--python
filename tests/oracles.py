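"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own code paths (and the library calls
standing behind them): everything is literal enumeration over node pairs and
triples, or the textbook step-up procedure.
"""

from __future__ import annotations

import math
from itertools import combinations


def bh_step_up(p: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg: sort, scale by m/rank, cummin from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    running = 1.0
    adj_sorted = [0.0] * m
    for i in range(m - 1, -1, -1):
        running = min(running, scaled[i])
        adj_sorted[i] = min(running, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


def zscore_sum(zs: list[float]) -> float:
    return sum(abs(z) for z in zs) / math.sqrt(len(zs))


def clustering_by_triples(edges: set[frozenset], nodes: list) -> float:
    """Average local clustering via exhaustive triple enumeration."""

    def connected(u, v):
        return frozenset((u, v)) in edges

    total = 0.0
    for v in nodes:
        nbrs = [u for u in nodes if u != v and connected(u, v)]
        if len(nbrs) < 2:
            continue
        pairs = list(combinations(nbrs, 2))
        closed = sum(1 for a, b in pairs if connected(a, b))
        total += closed / len(pairs)
    return total / len(nodes)


def two_module_q(edges: set[frozenset], s1: list, s2: list) -> float:
    """Literal within-module double sum over ordered pairs of the induced union."""
    union = list(s1) + list(s2)

    def a(i, j):
        return 1.0 if i != j and frozenset((i, j)) in edges else 0.0

    deg = {i: sum(a(i, j) for j in union) for i in union}
    two_e = sum(deg.values())
    if two_e == 0:
        return 0.0
    q = 0.0
    for module in (s1, s2):
        for i in module:
            for j in module:
                q += a(i, j) - deg[i] * deg[j] / two_e
    return q / two_e


def pa_by_counting(optimised: set, actual: set, universe: set) -> float:
    tp = fp = tn = fn = 0
    for v in universe:
        if v in optimised and v in actual:
            tp += 1
        elif v in optimised:
            fp += 1
        elif v in actual:
            fn += 1
        else:
            tn += 1
    return 1.0 - (fn + fp) / (tn + tp)


def nmi_by_entropy(labels_o: list[int], labels_a: list[int]) -> float:
    """2 I(O;A) / (H(O) + H(A)) from explicit plug-in entropies."""
    n = len(labels_o)

    def dist(labels):
        counts: dict[int, int] = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        return {k: v / n for k, v in counts.items()}

    po, pa = dist(labels_o), dist(labels_a)
    joint: dict[tuple[int, int], float] = {}
    for lo, la in zip(labels_o, labels_a):
        joint[lo, la] = joint.get((lo, la), 0.0) + 1.0 / n
    mi = sum(
        pij * math.log(pij / (po[i] * pa[j])) for (i, j), pij in joint.items() if pij > 0
    )
    ho = -sum(p * math.log(p) for p in po.values())
    ha = -sum(p * math.log(p) for p in pa.values())
    if ho + ha == 0:
        return 1.0
    return 2 * mi / (ho + ha)
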