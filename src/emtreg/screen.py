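"""Quantification and classification of the kinase-inhibitor scattering screen.

A well's migratory (scatter) distance at each timepoint is a dispersion
statistic of its cell positions; its log2 fold change against the matched
untreated control is integrated over the 0–48 h time course (trapezoid) into
an AUC. Inhibitors are then classified per inducer by quantile rules on the
wild-type (WT) versus YWHAG-knockdown (KD) AUC distributions:

1. AUC <= 25th percentile in both WT and KD -> YWHAG-independent EMT inhibitor
2. AUC <= 25th percentile in WT but > 25th in KD -> YWHAG-dependent EMT inhibitor
3. AUC < 75th percentile in WT but >= 75th in KD -> YWHAG-dependent EMT activator

applied in order with first match winning; an inhibitor's final category is
kept only when both inducers agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "scatter_distance",
    "scatter_table",
    "migration_logfc_series",
    "auc",
    "classify_inhibitors",
    "summarize_kinases",
    "tumor_volume",
    "ScreenClassification",
    "UNTREATED",
    "CATEGORY_LABELS",
]

UNTREATED = "UNTREATED"
CATEGORY_LABELS = (
    "independent_inhibitor",
    "dependent_inhibitor",
    "dependent_activator",
    "unclassified",
)
DISTANCE_FLOOR_UM = 1e-6


def scatter_distance(points: np.ndarray, method: str = "centroid") -> float:
    """Scatter of a cell population at one well-timepoint, in µm.

    ``centroid`` (default): mean Euclidean distance of cells to their
    centroid. ``pairwise``: mean distance over all unordered cell pairs.
    A single cell has zero scatter; an empty set is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need a non-empty (n_cells, 2) coordinate array")
    if pts.shape[0] == 1:
        return 0.0
    if method == "centroid":
        centroid = pts.mean(axis=0)
        return float(np.linalg.norm(pts - centroid, axis=1).mean())
    if method == "pairwise":
        from scipy.spatial.distance import pdist

        return float(pdist(pts).mean())
    raise ValueError(f"unknown scatter method {method!r}")


def scatter_table(tracks: pd.DataFrame, method: str = "centroid") -> pd.DataFrame:
    """Per (genotype, inducer, inhibitor, replicate, time_h) scatter distances."""
    keys = ["genotype", "inducer", "inhibitor", "replicate", "time_h"]
    if method == "centroid":
        # vectorised: mean distance to the group centroid
        g = tracks.groupby(keys, sort=True, observed=True)
        cx = g["x"].transform("mean")
        cy = g["y"].transform("mean")
        d = np.hypot(tracks["x"] - cx, tracks["y"] - cy)
        out = d.groupby([tracks[k] for k in keys], observed=True).mean()
        counts = g.size()
        out[counts == 1] = 0.0
        return out.rename("distance").reset_index()
    rows = []
    for key, sub in tracks.groupby(keys, sort=True, observed=True):
        rows.append((*key, scatter_distance(sub[["x", "y"]].to_numpy(), method=method)))
    return pd.DataFrame(rows, columns=keys + ["distance"])


def migration_logfc_series(
    tracks: pd.DataFrame,
    genotype: str,
    inducer: str,
    inhibitor: str,
    method: str = "centroid",
    distances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate-averaged log2 fold change of scatter vs the untreated control.

    Per replicate and timepoint, logfc = log2(d_treated / mean control
    distance at that timepoint); replicates are averaged after the log
    transform. Distances below 1 pm are floored (and flagged) before the
    ratio. Returns a DataFrame with columns time_h, logfc, floored.
    """
    if distances is None:
        mask = (
            (tracks["genotype"] == genotype)
            & (tracks["inducer"] == inducer)
            & tracks["inhibitor"].isin([inhibitor, UNTREATED])
        )
        distances = scatter_table(tracks[mask], method=method)
    sel = (distances["genotype"] == genotype) & (distances["inducer"] == inducer)
    treated = distances[sel & (distances["inhibitor"] == inhibitor)]
    control = distances[sel & (distances["inhibitor"] == UNTREATED)]
    if control.empty:
        raise ValueError(f"no untreated control well for {genotype}/{inducer}")
    if treated.empty:
        raise ValueError(f"no well for {genotype}/{inducer}/{inhibitor}")

    ctrl_mean = control.groupby("time_h")["distance"].mean()
    missing = sorted(set(treated["time_h"]) - set(ctrl_mean.index))
    if missing:
        raise ValueError(
            f"untreated control for {genotype}/{inducer} lacks timepoint(s) {missing}"
        )
    d_t = treated["distance"].to_numpy()
    d_c = ctrl_mean.reindex(treated["time_h"]).to_numpy()
    floored = (d_t < DISTANCE_FLOOR_UM) | (d_c < DISTANCE_FLOOR_UM)
    ratio = np.maximum(d_t, DISTANCE_FLOOR_UM) / np.maximum(d_c, DISTANCE_FLOOR_UM)
    per_rep = treated.assign(logfc=np.log2(ratio), floored=floored)
    out = (
        per_rep.groupby("time_h", sort=True)
        .agg(logfc=("logfc", "mean"), floored=("floored", "any"))
        .reset_index()
    )
    return out


def auc(series: pd.DataFrame | tuple) -> float:
    """Trapezoidal integral of logfc over the time grid (log2-units·h, signed)."""
    if isinstance(series, pd.DataFrame):
        t = series["time_h"].to_numpy(dtype=float)
        y = series["logfc"].to_numpy(dtype=float)
    else:
        t, y = (np.asarray(v, dtype=float) for v in series)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return float(np.trapezoid(y, t))


def auc_table(tracks: pd.DataFrame, method: str = "centroid") -> pd.DataFrame:
    """AUC per (genotype, inducer, inhibitor) for the whole panel.

    Computes all scatter distances once, then the replicate-averaged logfc
    series and its AUC per well. Untreated controls are excluded from the
    output (they are the logfc reference).
    """
    distances = scatter_table(tracks, method=method)
    rows = []
    for (geno, ind), sub in distances.groupby(["genotype", "inducer"], sort=True):
        for inhibitor in sorted(set(sub["inhibitor"]) - {UNTREATED}):
            series = migration_logfc_series(
                tracks, geno, ind, inhibitor, method=method, distances=sub
            )
            rows.append((geno, ind, inhibitor, auc(series), bool(series["floored"].any())))
    return pd.DataFrame(rows, columns=["genotype", "inducer", "inhibitor", "auc", "floored"])


def logfc_matrix(tracks: pd.DataFrame, genotype: str, inducer: str, method: str = "centroid") -> pd.DataFrame:
    """Heatmap-ready time x inhibitor log2-fold-change matrix for one panel."""
    distances = scatter_table(
        tracks[(tracks["genotype"] == genotype) & (tracks["inducer"] == inducer)], method=method
    )
    cols = {}
    for inhibitor in sorted(set(distances["inhibitor"]) - {UNTREATED}):
        s = migration_logfc_series(tracks, genotype, inducer, inhibitor, method=method, distances=distances)
        cols[inhibitor] = s.set_index("time_h")["logfc"]
    return pd.DataFrame(cols)


@dataclass
class ScreenClassification:
    """Per-inducer and final YWHAG-dependence categories with thresholds."""

    per_inducer: pd.DataFrame  # inducer, inhibitor, auc_WT, auc_KD, category
    final: pd.DataFrame  # inhibitor index; category
    thresholds: pd.DataFrame  # inducer index; q25_WT, q25_KD, q75_WT, q75_KD

    def counts(self) -> pd.Series:
        return self.final["category"].value_counts()


def _classify_one(a_wt: float, a_kd: float, q25w: float, q25k: float, q75w: float, q75k: float) -> str:
    if a_wt <= q25w and a_kd <= q25k:
        return "independent_inhibitor"
    if a_wt <= q25w and a_kd > q25k:
        return "dependent_inhibitor"
    if a_wt < q75w and a_kd >= q75k:
        return "dependent_activator"
    return "unclassified"


def classify_inhibitors(aucs: pd.DataFrame) -> ScreenClassification:
    """Apply the quantile criteria per inducer, then intersect across inducers.

    ``aucs`` is the :func:`auc_table` output (or any frame with genotype,
    inducer, inhibitor, auc). Percentiles are linear-interpolation quantiles
    of each (genotype, inducer) AUC distribution over the inhibitor panel.
    The final category is the per-inducer category when identical under all
    inducers, else ``unclassified``.
    """
    per_rows = []
    thr_rows = []
    for inducer, sub in aucs.groupby("inducer", sort=True):
        wt = sub[sub["genotype"] == "WT"].set_index("inhibitor")["auc"]
        kd = sub[sub["genotype"] == "KD"].set_index("inhibitor")["auc"]
        missing = set(wt.index) ^ set(kd.index)
        if missing:
            raise ValueError(
                f"{inducer}: WT and KD panels differ; unmatched inhibitors {sorted(missing)}"
            )
        if wt.nunique() < 2 or kd.nunique() < 2:
            raise ValueError(f"{inducer}: degenerate AUC panel (need >=2 distinct values)")
        q25w, q75w = np.percentile(wt, [25, 75])
        q25k, q75k = np.percentile(kd, [25, 75])
        thr_rows.append((inducer, q25w, q25k, q75w, q75k))
        for inhibitor in wt.index:
            cat = _classify_one(wt[inhibitor], kd[inhibitor], q25w, q25k, q75w, q75k)
            per_rows.append((inducer, inhibitor, wt[inhibitor], kd[inhibitor], cat))

    per_inducer = pd.DataFrame(
        per_rows, columns=["inducer", "inhibitor", "auc_WT", "auc_KD", "category"]
    )
    thresholds = pd.DataFrame(
        thr_rows, columns=["inducer", "q25_WT", "q25_KD", "q75_WT", "q75_KD"]
    ).set_index("inducer")

    def _final(cats: pd.Series) -> str:
        u = cats.unique()
        return u[0] if len(u) == 1 and u[0] != "unclassified" else "unclassified"

    final = (
        per_inducer.groupby("inhibitor")["category"].apply(_final).rename("category").to_frame()
    )
    return ScreenClassification(per_inducer=per_inducer, final=final, thresholds=thresholds)


def summarize_kinases(
    classification: ScreenClassification,
    inhibitor_kinase: pd.DataFrame,
    kinase_family: pd.DataFrame,
) -> pd.DataFrame:
    """Distinct-kinase counts per final category and kinase family.

    An inhibitor with several targets contributes each target to its family;
    inhibitors without annotation are counted under family ``unannotated``.
    The EMT-promoting arm (targets of classified inhibitors) versus
    EMT-attenuating arm (targets of activators) split is the ``arm`` column.
    """
    fam = kinase_family.set_index("kinase")["family"]
    merged = classification.final.reset_index().merge(inhibitor_kinase, on="inhibitor", how="left")
    merged["kinase"] = merged["kinase"].fillna("unannotated:" + merged["inhibitor"])
    merged["family"] = merged["kinase"].map(fam).fillna("unannotated")
    arm_of = {
        "independent_inhibitor": "EMT-promoting",
        "dependent_inhibitor": "EMT-promoting",
        "dependent_activator": "EMT-attenuating",
        "unclassified": "none",
    }
    merged["arm"] = merged["category"].map(arm_of)
    out = (
        merged.groupby(["category", "arm", "family"])["kinase"]
        .nunique()
        .rename("n_kinases")
        .reset_index()
    )
    # stable all-zero frame when nothing was classified
    return out[out["category"] != "unclassified"].reset_index(drop=True)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm³: 0.5 × length × width²  (length >= width).

    Swaps the arguments with a warning if width exceeds length.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; swapping measurements", stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2
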