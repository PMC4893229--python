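"""Gene-family construction by linkage clustering on a similarity graph.

All scores here are similarities (higher = more similar): clusters are
merged while the best inter-cluster linkage is >= tau.  Missing cross edges
count as similarity 0 — sparse graphs need a defined completion, and 0
matches "no detectable similarity".

Single linkage at threshold tau is exactly the connected components of the
graph restricted to edges with weight >= tau.  Average/complete linkage use
iterative agglomeration with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .decision import HomologyGraph
from .io import FamilyPartition
from .nc import ScoreTable

__all__ = [
    "LinkageConfig",
    "single_linkage",
    "agglomerative_linkage",
    "homologs_to_graph",
    "scores_to_graph",
]

Edge = tuple[str, str, float]

_METHODS = ("single", "average", "complete")
_WEIGHT_SOURCES = ("nc", "bits", "gfc", "h", "sys", "syc")


@dataclass(frozen=True)
class LinkageConfig:
    """Clustering strategy, similarity threshold and per-pair weight source.

    weight_source: 'nc' uses all edges weighted by NC; 'gfc' keeps only
    pairs called homologous by the decision boundary, weighted by NC (so
    thresholds stay on the NC scale and sweeps are comparable); 'bits' uses
    normalized bit scores; 'h' uses the decision value itself.
    """

    method: str = "single"
    tau: float = 0.5
    weight_source: str = "nc"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.weight_source not in _WEIGHT_SOURCES:
            raise ValueError(f"unknown weight source {self.weight_source!r}")


def single_linkage(
    edges: Iterable[Edge], tau: float, universe: Iterable[str]
) -> FamilyPartition:
    """Connected components of the graph restricted to edges with weight >= tau.

    Genes from ``universe`` with no qualifying edge become singletons.
    """
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for g1, g2, w in edges:
        graph.add_node(g1)
        graph.add_node(g2)
        if w >= tau:
            graph.add_edge(g1, g2)
    return FamilyPartition.from_clusters(nx.connected_components(graph))


def agglomerative_linkage(
    edges: Iterable[Edge], config: LinkageConfig, universe: Iterable[str]
) -> FamilyPartition:
    """Average or complete linkage agglomeration at similarity threshold tau.

    The two clusters with the highest inter-cluster linkage are merged until
    the best linkage drops below tau.  Average linkage is the mean weight
    over all cross pairs (absent edges = 0); complete linkage is the minimum
    cross-pair weight (absent = 0).  Equal-linkage ties are broken by the
    lexicographically least smallest member id, so results are reproducible.
    """
    if config.method not in ("average", "complete"):
        raise ValueError("agglomerative_linkage requires method 'average' or 'complete'")
    genes = sorted(set(universe) | {g for g1, g2, _ in edges for g in (g1, g2)})
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    if n == 0:
        return FamilyPartition({})

    # dense similarity with implicit-zero completion; desk-scale inputs only
    sim = np.zeros((n, n))
    for g1, g2, w in edges:
        i, j = index[g1], index[g2]
        if i != j:
            sim[i, j] = max(sim[i, j], w)
            sim[j, i] = sim[i, j]

    clusters: dict[int, list[str]] = {i: [g] for i, g in enumerate(genes)}
    sizes = {i: 1 for i in range(n)}
    link = sim.copy()  # inter-cluster linkage for live clusters
    live = set(range(n))

    def merge_key(i: int, j: int) -> tuple[str, str]:
        a, b = clusters[i][0], clusters[j][0]
        return (a, b) if a <= b else (b, a)

    while len(live) > 1:
        idx = sorted(live)
        sub = link[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        best = vals.max()
        if best < config.tau:
            break
        hits = np.flatnonzero(vals == best)
        candidates = [(idx[iu[0][h]], idx[iu[1][h]]) for h in hits]
        i, j = min(candidates, key=lambda p: merge_key(*p))
        for m in live:
            if m in (i, j):
                continue
            if config.method == "average":
                link[i, m] = (sizes[i] * link[i, m] + sizes[j] * link[j, m]) / (
                    sizes[i] + sizes[j]
                )
            else:  # complete: min over cross pairs
                link[i, m] = min(link[i, m], link[j, m])
            link[m, i] = link[i, m]
        clusters[i] = sorted(clusters[i] + clusters[j])
        sizes[i] += sizes[j]
        del clusters[j], sizes[j]
        live.discard(j)
    return FamilyPartition.from_clusters(clusters.values())


def homologs_to_graph(
    hom: HomologyGraph, weight_source: str = "nc", called_only: bool | None = None
) -> list[Edge]:
    """Project a homology graph onto weighted edges for clustering.

    'gfc' emits only pairs with call = True, weighted by NC; 'nc'/'sys'/
    'syc'/'h' emit all pairs with the named score.  ``called_only`` can
    override the filter explicitly.
    """
    if weight_source == "bits":
        raise ValueError("bit-score edges come from a ScoreTable; use scores_to_graph")
    if weight_source == "gfc":
        column, filt = "nc", True
    elif weight_source in ("nc", "sys", "syc", "h"):
        column, filt = weight_source, False
    else:
        raise ValueError(f"unknown weight source {weight_source!r}")
    if called_only is not None:
        filt = called_only
    return [
        (g1, g2, getattr(rec, column))
        for (g1, g2), rec in sorted(hom.items())
        if rec.call or not filt
    ]


def scores_to_graph(table: ScoreTable) -> list[Edge]:
    """All non-self normalized bit-score edges of a score table."""
    return [(g1, g2, table.score(g1, g2)) for g1, g2 in table.pairs()]


def cluster(
    edges: Iterable[Edge], config: LinkageConfig, universe: Iterable[str]
) -> FamilyPartition:
    """Dispatch to the configured linkage method."""
    if config.method == "single":
        return single_linkage(edges, config.tau, universe)
    return agglomerative_linkage(edges, config, universe)
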