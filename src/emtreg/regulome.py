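"""Term enrichment, semantic-similarity clustering and the function network.

The "regulome" is an enrichment-map-style network: enriched functional terms
from several query gene sets (the EMT consensus signature, the
YWHAG-dependent kinome and transcriptome) become nodes labelled by origin,
joined when their member genes overlap strongly enough — combined
coefficient ``k·Jaccard + (1-k)·overlap`` at the canonical 0.375 cutoff with
k = 0.5 — and grouped into annotated clusters.

Enrichment is the classic one-sided hypergeometric test with BH-FDR; term
semantic similarity is the Wang graph-based measure on the is_a DAG, with
best-match-average aggregation between term clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from ._stats import bh_adjust

__all__ = [
    "enrich",
    "wang_similarity",
    "wang_similarity_matrix",
    "bma_similarity",
    "cluster_terms",
    "combined_coefficient",
    "build_function_network",
    "EnrichmentResult",
    "FunctionNetwork",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one query gene set against a term annotation."""

    table: pd.DataFrame  # term index; name, k, K, n, N, pvalue, fdr
    origin: str
    alpha: float
    overlap_genes: dict[str, frozenset]  # term -> query ∩ term members

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.alpha]


def enrich(
    query,
    term_sets: dict[str, set[str]],
    universe: set[str] | None = None,
    term_names: dict[str, str] | None = None,
    alpha: float = 0.05,
    origin: str = "query",
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment with BH-FDR over all tested terms.

    Query genes outside the universe are dropped with a warning; terms are
    retained at ``fdr < alpha``. The universe defaults to the union of all
    term member sets.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    if universe is None:
        universe = set().union(*term_sets.values())
    stray = query - universe
    if stray:
        import warnings

        warnings.warn(f"dropping {len(stray)} query gene(s) outside the universe", stacklevel=2)
        query &= universe
        if not query:
            raise ValueError("no query genes remain inside the universe")

    N, n = len(universe), len(query)
    terms = sorted(term_sets)
    rows = []
    overlaps = {}
    for t in terms:
        members = term_sets[t] & universe
        K = len(members)
        hit = frozenset(members & query)
        k = len(hit)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((t, (term_names or {}).get(t, t), k, K, n, N, p))
        overlaps[t] = hit
    table = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "pvalue"]).set_index(
        "term"
    )
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return EnrichmentResult(table=table, origin=origin, alpha=alpha, overlap_genes=overlaps)


def _s_values(term: str, dag: nx.DiGraph, w: float) -> dict[str, float]:
    """Wang S-values of ``term`` over its ancestor set (edges child->parent)."""
    if term not in dag:
        raise KeyError(f"term {term!r} not in DAG")
    anc = nx.descendants(dag, term) | {term}  # ancestors under child->parent edges
    sub = dag.subgraph(anc)
    s = {term: 1.0}
    # process upward: children before parents
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        s[node] = max(w * s[c] for c in sub.predecessors(node))
    return s


def wang_similarity(t1: str, t2: str, dag: nx.DiGraph, edge_weight: float = 0.8) -> float:
    """Wang semantic similarity of two terms on the is_a DAG, in [0, 1].

    Each term's semantic contribution decays by ``edge_weight`` per is_a hop
    toward the root; similarity is the summed contribution of common
    ancestors relative to both terms' total semantic values.
    """
    s1 = _s_values(t1, dag, edge_weight)
    s2 = _s_values(t2, dag, edge_weight)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return num / (sum(s1.values()) + sum(s2.values()))


def wang_similarity_matrix(terms: list[str], dag: nx.DiGraph, edge_weight: float = 0.8) -> pd.DataFrame:
    svals = {t: _s_values(t, dag, edge_weight) for t in terms}
    totals = {t: sum(svals[t].values()) for t in terms}
    n = len(terms)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            common = set(svals[terms[i]]) & set(svals[terms[j]])
            num = sum(svals[terms[i]][t] + svals[terms[j]][t] for t in common)
            m[i, j] = m[j, i] = num / (totals[terms[i]] + totals[terms[j]])
    return pd.DataFrame(m, index=terms, columns=terms)


def bma_similarity(sim: pd.DataFrame, group_a: list[str], group_b: list[str]) -> float:
    """Best-match-average similarity between two groups of terms."""
    block = sim.loc[group_a, group_b].to_numpy()
    return float((block.max(axis=1).mean() + block.max(axis=0).mean()) / 2.0)


def cluster_terms(
    terms: list[str],
    dag: nx.DiGraph,
    k: int | str = "auto",
    edge_weight: float = 0.8,
) -> pd.DataFrame:
    """Ward hierarchical clustering of terms on 1 - Wang similarity.

    ``k`` is the number of clusters, or ``"auto"`` to pick it by the best
    silhouette score over 2..min(10, n-1). Returns a DataFrame (term index;
    cluster labels 0..k-1, relabelled by first appearance).
    """
    if len(terms) < 2:
        raise ValueError("need at least 2 terms to cluster")
    if isinstance(k, int) and k > len(terms):
        raise ValueError("k may not exceed the number of terms")
    sim = wang_similarity_matrix(list(terms), dag, edge_weight)
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")

    if k == "auto":
        from sklearn.metrics import silhouette_score

        best_k, best_score = 2, -np.inf
        for kk in range(2, min(10, len(terms) - 1) + 1):
            labels = fcluster(z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = fcluster(z, t=int(k), criterion="maxclust")
    # relabel by order of first appearance for determinism
    seen: dict[int, int] = {}
    relabeled = [seen.setdefault(lab, len(seen)) for lab in labels]
    return pd.DataFrame({"cluster": relabeled}, index=pd.Index(list(terms), name="term"))


def combined_coefficient(a, b, k: float = 0.5) -> float:
    """k·Jaccard + (1-k)·overlap coefficient of two gene sets."""
    from .hubs import set_overlap

    ov = set_overlap(a, b)
    return k * ov.jaccard + (1.0 - k) * ov.overlap_coefficient


_STOPWORDS = frozenset(
    "of the and in to a an for with by on process regulation activity "
    "term branch positive negative cellular".split()
)


@dataclass
class FunctionNetwork:
    """Enriched-term similarity network with origin labels and cluster annotations."""

    graph: nx.Graph
    clusters: pd.DataFrame  # term index; cluster, annotation
    cutoff: float
    combine_k: float

    def to_graphml(self, path: str) -> None:
        g = self.graph.copy()
        for node, data in g.nodes(data=True):
            data["genes"] = ",".join(sorted(data.pop("member_genes", ())))
        nx.write_graphml(g, path)

    def to_edge_tsv(self, path: str) -> None:
        rows = [
            {"term_a": a, "term_b": b, "similarity": d["similarity"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["term_a", "term_b", "similarity"]).to_csv(
            path, sep="\t", index=False
        )


def build_function_network(
    results: list[EnrichmentResult],
    cutoff: float = 0.375,
    combine_k: float = 0.5,
) -> FunctionNetwork:
    """Enrichment-map-style connectivity network over retained enriched terms.

    One node per retained (fdr < alpha) term per origin; similarity between
    two nodes is the combined coefficient of their query-overlap gene sets,
    and an edge is kept when it reaches ``cutoff``. Clusters are the
    connected components above the cutoff, annotated with the most frequent
    non-stopword tokens of their member term names.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    g = nx.Graph()
    members: dict[str, frozenset] = {}
    for res in results:
        for term in res.retained.index:
            node = f"{res.origin}:{term}"
            g.add_node(
                node,
                term=term,
                name=str(res.table.loc[term, "name"]),
                origin=res.origin,
                member_genes=res.overlap_genes[term],
            )
            members[node] = res.overlap_genes[term]
    nodes = sorted(g.nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 retained enriched terms overall")
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            sim = combined_coefficient(members[a], members[b], k=combine_k)
            if sim >= cutoff:
                g.add_edge(a, b, similarity=sim)

    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    rows = []
    for cid, comp in enumerate(comps):
        tokens: dict[str, int] = {}
        for node in comp:
            for tok in str(g.nodes[node]["name"]).lower().split():
                if tok not in _STOPWORDS and not tok.isdigit():
                    tokens[tok] = tokens.get(tok, 0) + 1
        top = sorted(tokens, key=lambda t: (-tokens[t], t))[:3]
        annotation = " ".join(top)
        for node in sorted(comp):
            g.nodes[node]["cluster"] = cid
            g.nodes[node]["annotation"] = annotation
            rows.append({"node": node, "cluster": cid, "annotation": annotation})
    clusters = pd.DataFrame(rows).set_index("node")
    return FunctionNetwork(graph=g, clusters=clusters, cutoff=cutoff, combine_k=combine_k)
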