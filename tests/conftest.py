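import numpy as np
import pandas as pd
import pytest

from emtreg.simulate import GeneratorConfig, gen_screen_tracks


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic world that keeps unit tests fast."""
    return GeneratorConfig(
        seed=11,
        n_genes=400,
        n_consistent_degs=30,
        n_decoy_degs=20,
        n_samples_per_group=6,
        n_inhibitors=40,
        n_kinases=20,
        n_planted_per_category=2,
        n_replicates=2,
        n_cells=20,
        n_terms=21,
        n_term_clusters=3,
        n_hubs=2,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return gen_screen_tracks(small_config)


def brute_force_maximal_cliques(graph):
    """Exhaustive subset enumeration oracle for maximal cliques (n <= ~15)."""
    from itertools import combinations

    nodes = list(graph.nodes)
    cliques = []
    for size in range(1, len(nodes) + 1):
        for subset in combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.append(frozenset(subset))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    return set(maximal)


def brute_force_mcc(graph):
    import math

    scores = {v: 0 for v in graph.nodes}
    for clique in brute_force_maximal_cliques(graph):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores
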