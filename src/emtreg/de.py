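"""Per-dataset differential expression and cross-dataset consistency voting.

The meta-integration rule is the bespoke step: a gene enters the consensus
EMT signature when it is significantly regulated in the *same* direction in
at least ``min_fraction`` of the supplied datasets (default 80%) and is
never significantly regulated in the opposite direction. The per-dataset DE
engine is deliberately simple — Welch's t on log2(CPM+1) with BH adjustment —
since externally computed DE tables (e.g. from DESeq2 reanalyses) can be
ingested instead via :func:`emtreg.io.read_de_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import CountDataset

__all__ = ["normalize_cpm", "simple_de", "integrate_consistency", "ConsensusDEGSet"]


def normalize_cpm(dataset: CountDataset) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to sum to 1e6."""
    counts = dataset.counts.astype(float)
    colsums = counts.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(
            f"{dataset.dataset_id}: sample(s) with zero total counts: {list(zero.index)}"
        )
    return counts / colsums * 1e6


def simple_de(dataset: CountDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Two-group differential expression on log2(CPM+1).

    log2FC is the treated-minus-control difference of group means on the
    log2(CPM+1) scale; p-values are two-sided Welch t-tests per gene, padj is
    BH across all genes. Returns a DataFrame (gene index; log2FC, pvalue,
    padj) with ``dataset_id`` in ``attrs``.
    """
    log_expr = np.log2(normalize_cpm(dataset) + 1.0)
    ctrl = log_expr[dataset.samples("control")].to_numpy()
    trt = log_expr[dataset.samples("treated")].to_numpy()

    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue)
    # constant genes (zero variance in both groups) are untestable -> p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    out = pd.DataFrame(
        {"log2FC": log2fc, "pvalue": pvals, "padj": bh_adjust(pvals)},
        index=dataset.counts.index,
    )
    out.attrs["dataset_id"] = dataset.dataset_id
    out.attrs["alpha"] = alpha
    return out


@dataclass
class ConsensusDEGSet:
    """Direction-consistent consensus DEG signature across datasets."""

    table: pd.DataFrame  # gene index; direction, support_count, support_fraction
    min_fraction: float
    alpha: float
    n_datasets: int
    dataset_ids: list[str]

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "down"])

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def integrate_consistency(
    tables: list[pd.DataFrame],
    min_fraction: float = 0.8,
    alpha: float = 0.05,
) -> ConsensusDEGSet:
    """Vote-counting integration of per-dataset DE tables.

    A gene is retained as "up" when the number of datasets calling it
    significantly up (padj < alpha, log2FC > 0) is at least
    ``min_fraction * n_datasets`` and no dataset calls it significantly
    down; symmetrically for "down". Genes absent from a dataset count as
    non-support there (the denominator is always the full number of supplied
    tables).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 DE tables to integrate")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    n = len(tables)

    up_votes: dict[str, int] = {}
    down_votes: dict[str, int] = {}
    universe: set[str] = set()
    for t in tables:
        universe.update(t.index)
        sig = t[t["padj"] < alpha]
        for g in sig.index[sig["log2FC"] > 0]:
            up_votes[g] = up_votes.get(g, 0) + 1
        for g in sig.index[sig["log2FC"] < 0]:
            down_votes[g] = down_votes.get(g, 0) + 1

    rows = []
    for g in sorted(universe):
        u, d = up_votes.get(g, 0), down_votes.get(g, 0)
        if u / n >= min_fraction and d == 0:
            rows.append((g, "up", u, u / n))
        elif d / n >= min_fraction and u == 0:
            rows.append((g, "down", d, d / n))
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "support_count", "support_fraction"]
    ).set_index("gene")
    return ConsensusDEGSet(
        table=table,
        min_fraction=min_fraction,
        alpha=alpha,
        n_datasets=n,
        dataset_ids=[t.attrs.get("dataset_id", f"table{i}") for i, t in enumerate(tables)],
    )
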