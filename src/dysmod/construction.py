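"""Experimental-data front end: DE filtering and disease-network assembly.

Starting from per-gene differential-expression tables (one per condition)
and a global interaction network, this module

1. adjusts raw p-values for multiple testing (Benjamini-Hochberg),
2. selects differentially expressed (DE) genes by adjusted p-value,
   expression level and absolute log2 fold change,
3. converts p-values of DE genes to z-scores via the upper-tail normal
   quantile ``z = Phi^-1(1 - p)`` (non-DE genes score exactly 0), and
4. assembles the disease network: all DE-DE interactions plus "hidden"
   linker nodes - non-DE genes interacting with at least two DE genes -
   restricted to the largest connected component.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "benjamini_hochberg",
    "select_differential_genes",
    "pvalue_to_z",
    "build_disease_network",
    "assemble_scored_network",
    "read_expression_table",
]

#: default DE thresholds: adjusted p, log2 mean expression index, |log2 FC|
P_THRESHOLD = 0.05
EXPR_THRESHOLD = 6.64
FC_THRESHOLD = 1.0


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_expression_table(path, adjust: bool = True) -> pd.DataFrame:
    """Read a per-gene expression TSV.

    Expected columns (header names): ``gene``, ``p`` (raw p-value),
    ``meanexpr`` (log2 mean expression index), ``logfc`` (log2 fold change)
    and optionally ``padj``; if ``padj`` is absent and ``adjust`` is true it
    is computed with Benjamini-Hochberg.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "p", "meanexpr", "logfc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if "padj" not in df.columns:
        if not adjust:
            raise ValueError("expression table has no padj column")
        df = df.assign(padj=benjamini_hochberg(df["p"].to_numpy()))
    return df


def select_differential_genes(
    records: pd.DataFrame,
    p_thresh: float = P_THRESHOLD,
    expr_thresh: float = EXPR_THRESHOLD,
    fc_thresh: float = FC_THRESHOLD,
) -> set[str]:
    """Genes with ``padj < p_thresh``, ``meanexpr > expr_thresh`` and ``|logfc| > fc_thresh``.

    The fold-change filter is two-sided: down-regulated genes qualify too.
    """
    if len(records) == 0:
        raise ValueError("empty expression table")
    mask = (
        (records["padj"] < p_thresh)
        & (records["meanexpr"] > expr_thresh)
        & (records["logfc"].abs() > fc_thresh)
    )
    return set(records.loc[mask, "gene"].astype(str))


def pvalue_to_z(p):
    """Upper-tail normal quantile ``z = Phi^-1(1 - p)``; strictly decreasing in p.

    Accepts a scalar or array; every value must lie strictly inside (0, 1)
    (callers clamp boundary values to the open interval first).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("p-values must lie strictly in (0, 1)")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def build_disease_network(
    interactions: Iterable[tuple[str, str]],
    de1: Iterable[str],
    de2: Iterable[str],
) -> nx.Graph:
    """Assemble the DE-plus-linker network from a global interactome.

    Keeps (i) every interaction whose two endpoints are both DE (in either
    condition), and (ii) every non-DE node with >= 2 DE interaction
    partners, together with its edges to those DE partners only. The result
    is restricted to its largest connected component.
    """
    de = set(map(str, de1)) | set(map(str, de2))
    if not de:
        raise ValueError("no differentially expressed genes supplied")
    g = nx.Graph()
    g.add_edges_from((str(u), str(v)) for u, v in interactions if str(u) != str(v))
    kept = nx.Graph()
    for u, v in g.edges:
        if u in de and v in de:
            kept.add_edge(u, v)
    for v in g.nodes:
        if v in de:
            continue
        de_partners = [u for u in g.neighbors(v) if u in de]
        if len(de_partners) >= 2:
            kept.add_edges_from((v, u) for u in de_partners)
    if kept.number_of_edges() == 0:
        raise ValueError("disease network is empty after filtering")
    lcc = max(nx.connected_components(kept), key=lambda c: (len(c), sorted(c)))
    dropped = kept.number_of_nodes() - len(lcc)
    if dropped:
        logger.info("dropped %d node(s) outside the largest connected component", dropped)
    return kept.subgraph(lcc).copy()


def assemble_scored_network(
    interactions: Iterable[tuple[str, str]],
    expr1: pd.DataFrame,
    expr2: pd.DataFrame,
    p_thresh: float = P_THRESHOLD,
    expr_thresh: float = EXPR_THRESHOLD,
    fc_thresh: float = FC_THRESHOLD,
) -> ScoredNetwork:
    """Full front end: DE selection, network assembly and z-score attachment.

    Z-scores of DE genes are converted from their raw p-values (clamped into
    the open unit interval); all other nodes score exactly 0 in the
    corresponding condition.
    """
    de1 = select_differential_genes(expr1, p_thresh, expr_thresh, fc_thresh)
    de2 = select_differential_genes(expr2, p_thresh, expr_thresh, fc_thresh)
    g = build_disease_network(interactions, de1, de2)
    eps = np.finfo(float).tiny

    def z_map(expr: pd.DataFrame, de: set[str]) -> dict[str, float]:
        pvals = dict(zip(expr["gene"].astype(str), expr["p"].astype(float)))
        out = {}
        for gene in de:
            p = min(max(pvals[gene], eps), 1.0 - 1e-16)
            out[gene] = pvalue_to_z(p)
        return out

    return ScoredNetwork(g.edges, z_map(expr1, de1), z_map(expr2, de2))
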