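"""Interaction-graph construction, maximal cliques and MCC hub ranking.

Maximal clique centrality (MCC) of a node v is the sum over all maximal
cliques C containing v of (|C| - 1)!. Nodes that dominate many or large
cliques dominate the ranking, which is how hub genes such as HSP90AA1 or
YWHAG surface from an EMT interaction network. Isolated nodes count as
singleton maximal cliques (0! = 1), keeping the ranking total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "build_graph",
    "maximal_cliques",
    "mcc_scores",
    "set_overlap",
    "SetOverlapResult",
]

logger = logging.getLogger(__name__)

DEFAULT_CLIQUE_CAP = 10**6


def build_graph(
    edge_lists: list[pd.DataFrame],
    restrict_to: set[str] | None = None,
) -> nx.Graph:
    """Union of edge lists into one simple undirected graph.

    Duplicate and reversed pairs merge, accumulating their ``source`` tags in
    the edge attribute ``sources`` (a sorted tuple). Self-loops are dropped
    with a warning. With ``restrict_to``, the induced subgraph on that gene
    set is returned (restriction nodes absent from every edge list are kept
    as isolated nodes only if they appeared as graph nodes).
    """
    g = nx.Graph()
    for df in edge_lists:
        for a, b, src in df[["node_a", "node_b", "source"]].itertuples(index=False):
            if a == b:
                logger.warning("dropping self-loop on %s (source %s)", a, src)
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["_sources"].add(src)
            else:
                g.add_edge(a, b, _sources={src})
    for _, _, data in g.edges(data=True):
        data["sources"] = tuple(sorted(data.pop("_sources")))
    if restrict_to is not None:
        g = g.subgraph(restrict_to).copy()
    return g


def maximal_cliques(graph: nx.Graph, cap: int = DEFAULT_CLIQUE_CAP) -> list[frozenset]:
    """All maximal cliques (Bron–Kerbosch with pivoting via networkx).

    Isolated nodes are reported as singleton cliques. Raises if the clique
    count exceeds ``cap`` (guards against pathological dense graphs).
    """
    cliques: list[frozenset] = []
    for c in nx.find_cliques(graph):
        cliques.append(frozenset(c))
        if len(cliques) > cap:
            raise RuntimeError(f"clique enumeration exceeded cap of {cap}")
    return cliques


def mcc_scores(
    graph: nx.Graph,
    top_k: int | None = None,
    cap: int = DEFAULT_CLIQUE_CAP,
) -> pd.DataFrame:
    """Maximal clique centrality per node, ranked descending.

    Returns a DataFrame (gene index; columns mcc, degree, rank) sorted by
    descending MCC then lexicographically by gene. Ties share the minimum
    rank. ``top_k`` slices the head of the ranking.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = {v: 0 for v in graph.nodes}
    for clique in maximal_cliques(graph, cap=cap):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    df = pd.DataFrame(
        {
            "gene": list(scores),
            "mcc": [scores[v] for v in scores],
            "degree": [graph.degree[v] for v in scores],
        }
    )
    df = df.sort_values(["mcc", "gene"], ascending=[False, True]).set_index("gene")
    df["rank"] = df["mcc"].rank(method="min", ascending=False).astype(int)
    if top_k is not None:
        df = df.head(top_k)
    return df


@dataclass(frozen=True)
class SetOverlapResult:
    """Exact overlap statistics between two gene sets."""

    size_a: int
    size_b: int
    intersection: int
    jaccard: float
    overlap_coefficient: float

    def to_dict(self) -> dict:
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "intersection": self.intersection,
            "jaccard": self.jaccard,
            "overlap_coefficient": self.overlap_coefficient,
        }


def set_overlap(a, b) -> SetOverlapResult:
    """Intersection count, Jaccard and overlap coefficient of two sets.

    Empty-set conventions: both coefficients are 0 when either set is empty.
    """
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    union = len(sa | sb)
    m = min(len(sa), len(sb))
    return SetOverlapResult(
        size_a=len(sa),
        size_b=len(sb),
        intersection=inter,
        jaccard=inter / union if union else 0.0,
        overlap_coefficient=inter / m if m else 0.0,
    )
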