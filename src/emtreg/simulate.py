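"""Synthetic-data generator with planted ground truth for every pipeline stage.

The generator emulates the inputs of an EMT (epithelial–mesenchymal
transition) hub-gene study: K RNA-seq count datasets with a planted fraction
of direction-consistent differentially expressed genes, protein-interaction
edge lists with planted clique-embedded hub genes, a 48-h time-lapse
cell-scattering screen over a kinase-inhibitor panel with planted
YWHAG-dependence categories, and a GO-like term annotation (GMT + shallow
is_a DAG) with planted functional clusters.

Every output is fully determined by ``GeneratorConfig.seed``; the returned
truth tables are sufficient to score downstream recovery without reading
generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import CountDataset, TRACK_COLUMNS

__all__ = [
    "GeneratorConfig",
    "gen_count_datasets",
    "gen_interactome",
    "gen_screen_tracks",
    "gen_term_annotation",
    "generate_all",
    "TIME_GRID_STEP_H",
    "CATEGORIES",
]

TIME_GRID_STEP_H = 4.0
CATEGORIES = ("independent_inhibitor", "dependent_inhibitor", "dependent_activator")

KINASE_FAMILIES = ("TK", "TKL", "AGC", "CAMK", "CMGC", "STE", "CK1", "Other")

# independent substreams so each generator is deterministic on its own
_STREAMS = {"plant": 0, "counts": 1, "interactome": 2, "screen": 3, "terms": 4}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic world.

    Defaults mirror the emulated study design: 5 expression datasets, a
    188-inhibitor screen targeting 130 kinases sampled every 4 h over 48 h,
    and 7 functional term clusters.
    """

    seed: int = 0
    n_datasets: int = 5
    n_genes: int = 1000
    n_samples_per_group: int = 6
    nb_mean: float = 100.0  # median of the log-normal gene-wise base means
    nb_dispersion: float = 0.1  # NB dispersion alpha: var = mu + alpha*mu^2
    n_consistent_degs: int = 100
    consistency_fraction: float = 1.0
    planted_log2fc: float = 2.0
    n_decoy_degs: int = 100  # direction-consistent but under-supported decoys
    decoy_fraction: float = 0.6
    n_hubs: int = 5
    n_inhibitors: int = 188
    n_kinases: int = 130
    n_timepoints: int = 13  # 0..48 h at 4 h steps
    scatter_noise_sd: float = 5.0  # µm, i.i.d. Gaussian on coordinates
    n_replicates: int = 3
    n_cells: int = 50
    n_planted_per_category: int = 10
    n_terms: int = 70
    n_term_clusters: int = 7

    def __post_init__(self) -> None:
        if min(self.n_datasets, self.n_genes, self.n_samples_per_group) <= 0:
            raise ValueError("dataset dimensions must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.n_consistent_degs + self.n_decoy_degs > self.n_genes:
            raise ValueError("planted DEGs exceed n_genes")
        if not 0.0 <= self.consistency_fraction <= 1.0:
            raise ValueError("consistency_fraction must lie in [0, 1]")
        if self.n_term_clusters > self.n_terms:
            raise ValueError("n_term_clusters may not exceed n_terms")
        if self.scatter_noise_sd <= 0:
            raise ValueError("scatter_noise_sd must be positive")
        if 3 * self.n_planted_per_category > self.n_inhibitors:
            raise ValueError("planted screen categories exceed the inhibitor panel")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    @property
    def genes(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def time_grid(self) -> np.ndarray:
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints on the 4 h grid")
        return np.arange(self.n_timepoints) * TIME_GRID_STEP_H

    @property
    def inhibitors(self) -> list[str]:
        return [f"INH{i:04d}" for i in range(self.n_inhibitors)]

    def to_dict(self) -> dict:
        return asdict(self)


def _plant_genes(config: GeneratorConfig) -> pd.DataFrame:
    """Planted per-gene truth: direction and per-dataset participation.

    Deterministic in the seed and shared between the count and interactome
    generators, so hub plants land on consistently regulated genes.
    """
    rng = config.rng("plant")
    genes = np.array(config.genes)
    order = rng.permutation(config.n_genes)
    consistent = genes[order[: config.n_consistent_degs]]
    decoys = genes[order[config.n_consistent_degs : config.n_consistent_degs + config.n_decoy_degs]]

    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    truth["direction"] = "null"
    truth["planted_class"] = "null"
    truth.loc[consistent, "planted_class"] = "consistent"
    truth.loc[decoys, "planted_class"] = "decoy"
    # alternate directions deterministically within each planted block
    truth.loc[consistent, "direction"] = ["up" if i % 2 == 0 else "down" for i in range(len(consistent))]
    truth.loc[decoys, "direction"] = ["up" if i % 2 == 0 else "down" for i in range(len(decoys))]

    k_cons = math.ceil(config.consistency_fraction * config.n_datasets)
    k_decoy = math.ceil(config.decoy_fraction * config.n_datasets)
    participation = np.zeros((config.n_genes, config.n_datasets), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for block, k in ((consistent, k_cons), (decoys, k_decoy)):
        for g in block:
            ds = rng.choice(config.n_datasets, size=k, replace=False)
            participation[gene_pos[g], ds] = True
    for d in range(config.n_datasets):
        truth[f"in_dataset_{d}"] = participation[:, d]
    return truth


def gen_count_datasets(config: GeneratorConfig) -> tuple[list[CountDataset], pd.DataFrame]:
    """Simulate ``n_datasets`` negative-binomial count datasets.

    Gene-wise base means are log-normal around ``nb_mean``; a planted DEG
    multiplies its treated-group mean by ``2**planted_log2fc`` (direction
    "up") or its reciprocal ("down") in exactly the datasets its truth row
    marks, and has no effect elsewhere. Dispersion is shared across genes.
    """
    truth = _plant_genes(config)
    rng = config.rng("counts")
    genes = config.genes
    n = config.n_samples_per_group
    alpha = config.nb_dispersion

    base_means = np.exp(rng.normal(np.log(config.nb_mean), 1.0, size=config.n_genes))
    dir_sign = truth["direction"].map({"up": 1.0, "down": -1.0, "null": 0.0}).to_numpy()

    datasets = []
    for d in range(config.n_datasets):
        active = truth[f"in_dataset_{d}"].to_numpy()
        effect = np.where(active, 2.0 ** (dir_sign * config.planted_log2fc), 1.0)
        mu_ctrl = np.repeat(base_means[:, None], n, axis=1)
        mu_trt = mu_ctrl * effect[:, None]
        mu = np.concatenate([mu_ctrl, mu_trt], axis=1)
        # NB(mu, alpha): var = mu + alpha mu^2  ->  size r = 1/alpha
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        cols = [f"ctrl_{i}" for i in range(n)] + [f"trt_{i}" for i in range(n)]
        df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cols)
        groups = pd.Series(["control"] * n + ["treated"] * n, index=cols, name="group")
        datasets.append(CountDataset(dataset_id=f"DS{d}", counts=df, groups=groups))
    return datasets, truth


def gen_interactome(
    config: GeneratorConfig,
    n_background: int = 200,
    background_degree: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate three protein-interaction edge lists with planted hub genes.

    Each of the ``n_hubs`` planted hubs sits in 3 node-disjoint cliques of
    size 4 built from consistently regulated genes, so its maximal-clique
    centrality is 3·3! = 18 — separable by construction from the sparse
    Erdős–Rényi background laid over other genes. Edges are split across
    three source tags emulating independent interaction databases.

    Returns (edge DataFrame with columns node_a/node_b/source, hub truth).
    """
    gene_truth = _plant_genes(config)
    consistent = list(gene_truth.index[gene_truth["planted_class"] == "consistent"])
    need = config.n_hubs * 10  # hub + 3 cliques x 3 partners
    if len(consistent) < need:
        raise ValueError(f"need >= {need} consistent planted DEGs to embed {config.n_hubs} hubs")
    rng = config.rng("interactome")

    hubs = consistent[: config.n_hubs]
    partners = consistent[config.n_hubs : need]
    edges: list[tuple[str, str]] = []
    for h_idx, hub in enumerate(hubs):
        for c in range(3):
            members = [hub] + partners[h_idx * 9 + c * 3 : h_idx * 9 + (c + 1) * 3]
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((members[i], members[j]))

    clique_nodes = set(hubs) | set(partners)
    pool = [g for g in gene_truth.index if g not in clique_nodes]
    bg_nodes = list(rng.choice(pool, size=min(n_background, len(pool)), replace=False))
    p_edge = background_degree / max(len(bg_nodes) - 1, 1)
    for i in range(len(bg_nodes)):
        draws = rng.random(len(bg_nodes) - i - 1)
        for off, u in enumerate(draws):
            if u < p_edge:
                edges.append((bg_nodes[i], bg_nodes[i + 1 + off]))

    sources = np.array(["stringdb", "bioplex", "ania"])
    assign = rng.integers(0, 3, size=len(edges))
    edge_df = pd.DataFrame(
        {
            "node_a": [a for a, _ in edges],
            "node_b": [b for _, b in edges],
            "source": sources[assign],
        }
    )
    hub_truth = pd.DataFrame({"gene": list(gene_truth.index)})
    hub_truth["is_hub"] = hub_truth["gene"].isin(hubs)
    return edge_df, hub_truth.set_index("gene")


# planted kinetic model of the scattering screen (µm, µm/h)
_BASE_SCATTER_UM = 20.0
_EMT_GROWTH_UM_PER_H = 2.0
_SUPPRESSION_FACTOR = 0.35  # planted inhibitors slow scatter growth to 35%
_ACTIVATION_FACTOR = 1.8  # planted activators speed KD scatter growth
_NULL_JITTER_SD = 0.15  # lognormal sd of per-inhibitor growth jitter (nulls)


def gen_screen_tracks(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the time-lapse scattering screen over the inhibitor panel.

    Wells are genotype (WT / KD) x inducer (DMOG / TGFB) x (inhibitor or
    UNTREATED control) x replicate; each well holds ``n_cells`` cells imaged
    on the 0–48 h grid. Untreated EMT wells scatter linearly with time;
    planted categories modulate the growth rate:

    - ``independent_inhibitor``: suppressed growth in both genotypes
    - ``dependent_inhibitor``: suppressed in WT only
    - ``dependent_activator``: accelerated in KD only

    Unplanted inhibitors carry a small lognormal per-inhibitor growth jitter
    (shared across genotypes and inducers) that gives the AUC distribution
    realistic spread; planted inhibitors carry their exact planted effect.
    Cells are placed as an isotropic Gaussian cloud whose expected
    mean-distance-to-centroid equals the planted scatter, then perturbed by
    ``scatter_noise_sd`` positional noise.

    Returns (tracks, inhibitor truth, inhibitor->kinase, kinase->family).
    """
    rng = config.rng("screen")
    time_grid = config.time_grid
    inhibitors = config.inhibitors

    npc = config.n_planted_per_category
    planted = rng.choice(config.n_inhibitors, size=3 * npc, replace=False)
    category = np.array(["null"] * config.n_inhibitors, dtype=object)
    for c, cat in enumerate(CATEGORIES):
        category[planted[c * npc : (c + 1) * npc]] = cat

    jitter = np.exp(rng.normal(0.0, _NULL_JITTER_SD, size=config.n_inhibitors))
    jitter[category != "null"] = 1.0

    # per (inhibitor, genotype) growth multiplier
    mult = {"WT": jitter.copy(), "KD": jitter.copy()}
    mult["WT"][category == "independent_inhibitor"] = _SUPPRESSION_FACTOR
    mult["KD"][category == "independent_inhibitor"] = _SUPPRESSION_FACTOR
    mult["WT"][category == "dependent_inhibitor"] = _SUPPRESSION_FACTOR
    mult["KD"][category == "dependent_activator"] = _ACTIVATION_FACTOR

    treatments = ["UNTREATED"] + inhibitors
    genotypes = ["WT", "KD"]
    inducers = ["DMOG", "TGFB"]
    n_cells = config.n_cells
    n_rep = config.n_replicates

    n_wells = len(genotypes) * len(inducers) * len(treatments) * n_rep
    n_rows = n_wells * len(time_grid) * n_cells

    geno_col = np.empty(n_rows, dtype=object)
    ind_col = np.empty(n_rows, dtype=object)
    trt_col = np.empty(n_rows, dtype=object)
    rep_col = np.empty(n_rows, dtype=np.int64)
    t_col = np.empty(n_rows)
    cell_col = np.empty(n_rows, dtype=np.int64)
    x_col = np.empty(n_rows)
    y_col = np.empty(n_rows)

    # E[mean distance to centroid] for an isotropic 2D Gaussian of per-axis sd s
    # is s*sqrt(pi/2); invert to place cells at a planted scatter level.
    scale_factor = 1.0 / math.sqrt(math.pi / 2.0)

    pos = 0
    block = len(time_grid) * n_cells
    for geno in genotypes:
        for inducer in inducers:
            for t_idx, trt in enumerate(treatments):
                m = 1.0 if trt == "UNTREATED" else mult[geno][t_idx - 1]
                target = _BASE_SCATTER_UM + m * _EMT_GROWTH_UM_PER_H * time_grid
                sigma = target * scale_factor
                for rep in range(n_rep):
                    sl = slice(pos, pos + block)
                    geno_col[sl] = geno
                    ind_col[sl] = inducer
                    trt_col[sl] = trt
                    rep_col[sl] = rep
                    t_col[sl] = np.repeat(time_grid, n_cells)
                    cell_col[sl] = np.tile(np.arange(n_cells), len(time_grid))
                    sd = np.repeat(sigma, n_cells)
                    xy = rng.normal(0.0, 1.0, size=(block, 2)) * sd[:, None]
                    xy += rng.normal(0.0, config.scatter_noise_sd, size=(block, 2))
                    x_col[sl] = xy[:, 0]
                    y_col[sl] = xy[:, 1]
                    pos += block

    tracks = pd.DataFrame(
        {
            "genotype": geno_col,
            "inducer": ind_col,
            "inhibitor": trt_col,
            "replicate": rep_col,
            "time_h": t_col,
            "cell_id": cell_col,
            "x": x_col,
            "y": y_col,
        }
    )[TRACK_COLUMNS]

    inhibitor_truth = pd.DataFrame(
        {"inhibitor": inhibitors, "planted_category": category}
    ).set_index("inhibitor")

    # annotation tables: every kinase targeted by >=1 inhibitor
    kinases = [f"KIN{i:03d}" for i in range(config.n_kinases)]
    k_assign = np.concatenate(
        [
            np.arange(config.n_kinases),
            rng.integers(0, config.n_kinases, size=max(config.n_inhibitors - config.n_kinases, 0)),
        ]
    )[: config.n_inhibitors]
    rng.shuffle(k_assign)
    inhibitor_kinase = pd.DataFrame(
        {"inhibitor": inhibitors, "kinase": [kinases[k] for k in k_assign]}
    )
    fam = rng.integers(0, len(KINASE_FAMILIES), size=config.n_kinases)
    kinase_family = pd.DataFrame(
        {"kinase": kinases, "family": [KINASE_FAMILIES[f] for f in fam]}
    )
    return tracks, inhibitor_truth, inhibitor_kinase, kinase_family


def gen_term_annotation(
    config: GeneratorConfig,
    core_size: int = 20,
    unique_size: int = 10,
):
    """Simulate a GO-like term annotation with planted functional clusters.

    Terms are organized under ``n_term_clusters`` depth-1 branches of a
    rooted is_a DAG. Every term in a branch contains that branch's core gene
    set (so within-branch sharing is >= core/(core+unique) = 2/3) plus
    term-unique genes; branch gene pools are disjoint, so cross-branch
    sharing is 0. The first branch's core is seeded with planted consistent
    DEGs so enrichment of a recovered DEG signature lights it up.

    Returns (term->genes, term->name, DAG, term truth DataFrame).
    """
    import networkx as nx

    gene_truth = _plant_genes(config)
    rng = config.rng("terms")
    genes = np.array(config.genes)
    consistent = list(gene_truth.index[gene_truth["planted_class"] == "consistent"])

    n_branches = config.n_term_clusters
    per_gene_need = n_branches * core_size + config.n_terms * unique_size
    if per_gene_need > config.n_genes:
        raise ValueError("gene universe too small for the requested term annotation")

    # disjoint branch cores + term-unique pools; branch 0 core = planted DEGs
    taken: set[str] = set()
    cores: list[list[str]] = []
    first_core = consistent[:core_size]
    cores.append(first_core)
    taken.update(first_core)
    remaining = np.array([g for g in genes if g not in taken])
    rng.shuffle(remaining)
    cursor = 0
    for _ in range(1, n_branches):
        cores.append(list(remaining[cursor : cursor + core_size]))
        cursor += core_size
    unique_pool = remaining[cursor:]

    # spread terms over branches as evenly as possible
    branch_of = [i % n_branches for i in range(config.n_terms)]
    dag = nx.DiGraph()
    root = "T:ROOT"
    dag.add_node(root, name="biological process")
    for b in range(n_branches):
        bid = f"T:BR{b:02d}"
        dag.add_node(bid, name=f"branch {b} process")
        dag.add_edge(bid, root)

    term_sets: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    rows = []
    u_cursor = 0
    vocab = [
        "signaling", "response", "division", "metabolic", "developmental",
        "organismal", "modification", "transport", "stress", "adhesion",
    ]
    for i in range(config.n_terms):
        b = branch_of[i]
        tid = f"T:{i:04d}"
        uniq = list(unique_pool[u_cursor : u_cursor + unique_size])
        u_cursor += unique_size
        term_sets[tid] = set(cores[b]) | set(uniq)
        term_names[tid] = f"branch{b} {vocab[b % len(vocab)]} term {i}"
        dag.add_node(tid, name=term_names[tid])
        dag.add_edge(tid, f"T:BR{b:02d}")
        rows.append({"term": tid, "planted_cluster": b})
    term_truth = pd.DataFrame(rows).set_index("term")
    return term_sets, term_names, dag, term_truth


def generate_all(config: GeneratorConfig, outdir: str) -> dict[str, object]:
    """Generate every synthetic input and write it under ``outdir``.

    Writes per-dataset count/group TSVs, three edge-list TSVs, the cell-track
    CSV, inhibitor/kinase annotation TSVs, the GMT, the OBO-subset DAG, and
    TSV truth tables. Returns the in-memory objects keyed by name.
    """
    import os

    from . import io as eio

    os.makedirs(outdir, exist_ok=True)
    datasets, gene_truth = gen_count_datasets(config)
    for ds in datasets:
        eio.write_counts(
            ds,
            os.path.join(outdir, f"{ds.dataset_id}_counts.tsv"),
            os.path.join(outdir, f"{ds.dataset_id}_groups.tsv"),
        )
    gene_truth.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")

    edges, hub_truth = gen_interactome(config)
    for src in ("stringdb", "bioplex", "ania"):
        eio.write_edge_list(edges[edges["source"] == src], os.path.join(outdir, f"edges_{src}.tsv"))
    hub_truth.to_csv(os.path.join(outdir, "truth_hubs.tsv"), sep="\t")

    tracks, inhib_truth, inhib_kinase, kinase_family = gen_screen_tracks(config)
    eio.write_tracks(tracks, os.path.join(outdir, "tracks.csv"))
    inhib_truth.to_csv(os.path.join(outdir, "truth_inhibitors.tsv"), sep="\t")
    inhib_kinase.to_csv(os.path.join(outdir, "inhibitor_kinase.tsv"), sep="\t", index=False)
    kinase_family.to_csv(os.path.join(outdir, "kinase_family.tsv"), sep="\t", index=False)

    term_sets, term_names, dag, term_truth = gen_term_annotation(config)
    eio.write_gmt(term_sets, term_names, os.path.join(outdir, "terms.gmt"))
    eio.write_obo(dag, os.path.join(outdir, "terms.obo"))
    term_truth.to_csv(os.path.join(outdir, "truth_terms.tsv"), sep="\t")

    return {
        "datasets": datasets,
        "gene_truth": gene_truth,
        "edges": edges,
        "hub_truth": hub_truth,
        "tracks": tracks,
        "inhibitor_truth": inhib_truth,
        "inhibitor_kinase": inhib_kinase,
        "kinase_family": kinase_family,
        "term_sets": term_sets,
        "term_names": term_names,
        "term_dag": dag,
        "term_truth": term_truth,
    }
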