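"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
- count matrix TSV: first column ``gene``, one column per sample; companion
  two-column TSV mapping sample -> group (``control`` / ``treated``)
- DE table TSV: columns ``gene, log2FC, pvalue, padj``
- edge-list TSV: three columns ``node_a, node_b, source``; ``#`` comment lines
- cell-track CSV: ``genotype,inducer,inhibitor,replicate,time_h,cell_id,x,y``
- GMT: tab-separated ``term, description, gene...``
- OBO subset: ``[Term]`` stanzas with ``id``, ``name`` and ``is_a`` tags only
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "CountDataset",
    "read_counts",
    "write_counts",
    "read_de_table",
    "write_de_table",
    "read_edge_list",
    "write_edge_list",
    "read_tracks",
    "write_tracks",
    "read_gmt",
    "write_gmt",
    "read_obo",
    "write_obo",
    "read_gene_list",
    "write_gene_list",
]

TRACK_COLUMNS = ["genotype", "inducer", "inhibitor", "replicate", "time_h", "cell_id", "x", "y"]


@dataclass
class CountDataset:
    """One study's gene x sample count matrix with a control/treated split."""

    dataset_id: str
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    groups: pd.Series  # sample -> {"control", "treated"}

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate gene ids")
        if not set(self.groups.index) == set(self.counts.columns):
            raise ValueError(f"{self.dataset_id}: group labels do not match samples")
        bad = set(self.groups.unique()) - {"control", "treated"}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {sorted(bad)}")
        for g in ("control", "treated"):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"{self.dataset_id}: fewer than 2 samples in group {g!r}")

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def write_counts(ds: CountDataset, counts_path: str, groups_path: str) -> None:
    out = ds.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t")
    g = ds.groups.rename("group").to_frame()
    g.index.name = "sample"
    g.to_csv(groups_path, sep="\t")


def read_counts(counts_path: str, groups_path: str, dataset_id: str | None = None) -> CountDataset:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(counts_path))[0]
    return CountDataset(dataset_id=dataset_id, counts=counts, groups=groups)


_DE_COLUMNS = ["gene", "log2FC", "pvalue", "padj"]


def read_de_table(path: str, dataset_id: str | None = None) -> pd.DataFrame:
    """Read and validate a per-dataset differential-expression table.

    Returns a DataFrame indexed by gene with columns log2FC, pvalue, padj and
    a ``dataset_id`` attribute in ``df.attrs``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    for col in ("pvalue", "padj"):
        vals = df[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    df = df.set_index("gene")[["log2FC", "pvalue", "padj"]]
    df.attrs["dataset_id"] = dataset_id or os.path.splitext(os.path.basename(path))[0]
    return df


def write_de_table(df: pd.DataFrame, path: str) -> None:
    out = df.reset_index()
    out.columns = _DE_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str, source: str | None = None) -> pd.DataFrame:
    """Three-column edge list (node_a, node_b, source); '#' lines ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2 and source is not None:
                parts.append(source)
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            rows.append(parts)
    return pd.DataFrame(rows, columns=["node_a", "node_b", "source"])


def write_edge_list(df: pd.DataFrame, path: str) -> None:
    df[["node_a", "node_b", "source"]].to_csv(path, sep="\t", index=False, header=False)


def read_tracks(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track column(s) {missing}")
    return df[TRACK_COLUMNS]


def write_tracks(df: pd.DataFrame, path: str) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


def read_gmt(path: str) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file into (term -> gene set, term -> description)."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description and >=1 gene")
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = set(g for g in genes if g)
            names[term] = desc
    return sets, names


def write_gmt(sets: dict[str, set[str]], names: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for term in sets:
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{names.get(term, term)}\t{genes}\n")


def read_obo(path: str) -> nx.DiGraph:
    """Parse an OBO-subset file (id/name/is_a stanzas) into a child->parent DAG.

    Edges point from child term to parent term; node attribute ``name`` holds
    the term label.
    """
    dag = nx.DiGraph()
    term_id: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                term_id = None
            elif line.startswith("id:"):
                term_id = line[3:].strip()
                dag.add_node(term_id)
            elif line.startswith("name:") and term_id is not None:
                dag.nodes[term_id]["name"] = line[5:].strip()
            elif line.startswith("is_a:") and term_id is not None:
                parent = line[5:].strip().split("!")[0].strip()
                dag.add_edge(term_id, parent)
    if dag.number_of_nodes() and not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: is_a relation contains a cycle")
    return dag


def write_obo(dag: nx.DiGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for node in dag.nodes:
            fh.write("\n[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {dag.nodes[node].get('name', node)}\n")
            for parent in sorted(dag.successors(node)):
                fh.write(f"is_a: {parent}\n")


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
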