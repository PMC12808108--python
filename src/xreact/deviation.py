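"""Per-cell transcriptional deviation from a control expression profile.

For each cluster, the differentially expressed genes between case and
control define a signature; each cell's deviation is the mean fold change
over those genes relative to the cluster's control mean, using the
reciprocal fold change for downregulated genes.  A cell matching the
control profile scores 1; larger values mean larger departures.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from xreact.ase_bulk import _bh
from xreact.sc_allelic import bin_by_pseudotime


def control_means(
    expression: pd.DataFrame,
    control_cells,
    clusters: pd.Series,
) -> dict[str, pd.Series]:
    """Per-cluster, per-gene arithmetic mean over control cells.

    ``expression`` is cells x genes; clusters without any control cell are
    excluded with a warning.
    """
    control_cells = [c for c in control_cells if c in expression.index]
    ctrl_clusters = clusters.loc[control_cells]
    out: dict[str, pd.Series] = {}
    for cluster in clusters.unique():
        members = ctrl_clusters.index[ctrl_clusters == cluster]
        if len(members) == 0:
            warnings.warn(f"cluster {cluster!r} has no control cells; excluded")
            continue
        out[cluster] = expression.loc[members].mean(axis=0)
    return out


def cell_deviation(
    cell_expression: pd.Series,
    ctrl_means: pd.Series,
    de_table: pd.DataFrame,
    epsilon: float = 1e-9,
) -> float:
    """Mean fold change of a cell over the control mean on the DE genes.

    Upregulated genes contribute (expr + eps) / (ctrl + eps), downregulated
    genes the reciprocal.
    """
    if de_table.empty:
        raise ValueError("DE table is empty for this cluster")
    genes = de_table["gene"].to_numpy()
    direction = de_table["direction"].to_numpy()
    expr = cell_expression.reindex(genes).to_numpy(dtype=float)
    ctrl = ctrl_means.reindex(genes).to_numpy(dtype=float)
    fc = (expr + epsilon) / (ctrl + epsilon)
    fc = np.where(direction == "down", 1.0 / fc, fc)
    return float(fc.mean())


def deviation_scores(
    expression: pd.DataFrame,
    clusters: pd.Series,
    control_cells,
    de_table: pd.DataFrame,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Deviation of every cell, using its cluster's DE genes and control mean.

    ``de_table`` may carry a ``cluster`` column for cluster-specific
    signatures; otherwise the same signature is used everywhere.  Cells in
    clusters without controls or without DE genes are skipped with a
    warning.
    """
    ctrl = control_means(expression, control_cells, clusters)
    per_cluster_de: Mapping[str, pd.DataFrame]
    if "cluster" in de_table.columns and de_table["cluster"].notna().any():
        per_cluster_de = {k: g for k, g in de_table.groupby("cluster")}
    else:
        per_cluster_de = {c: de_table for c in ctrl}

    rows = []
    for cluster, members in clusters.groupby(clusters):
        if cluster not in ctrl:
            continue
        de = per_cluster_de.get(cluster)
        if de is None or de.empty:
            warnings.warn(f"cluster {cluster!r} has no DE genes; skipped")
            continue
        genes = de["gene"].to_numpy()
        down = (de["direction"].to_numpy() == "down")
        sub = expression.loc[members.index, genes].to_numpy(dtype=float)
        ctrl_vec = ctrl[cluster].reindex(genes).to_numpy(dtype=float)
        fc = (sub + epsilon) / (ctrl_vec + epsilon)
        fc[:, down] = 1.0 / fc[:, down]
        dev = fc.mean(axis=1)
        for cell, d in zip(members.index, dev):
            rows.append({"cell": cell, "cluster": cluster, "deviation": d})
    return pd.DataFrame(rows)


def aggregate_deviation(
    deviations: pd.DataFrame,
    by: str = "cluster",
    pseudotime: pd.Series | None = None,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Group means of per-cell deviation, by cluster or pseudotime bin."""
    if by == "cluster":
        out = (
            deviations.groupby("cluster")["deviation"]
            .agg(mean="mean", n="count")
            .reset_index()
        )
        return out
    if by == "pseudotime":
        if pseudotime is None:
            raise ValueError("pseudotime series required for pseudotime aggregation")
        t = pseudotime.reindex(deviations["cell"]).to_numpy(dtype=float)
        return bin_by_pseudotime(deviations["deviation"].to_numpy(), t, n_bins)
    raise ValueError(f"unknown grouping {by!r}")


def rank_sum_de(
    expression: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    control_label: str,
    alpha: float = 0.01,
    min_abs_log2fc: float = 2.0,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum differential expression.

    Per-gene two-sided rank-sum p (BH-adjusted) and log2 fold change of
    group means with a pseudocount; genes passing adjusted p < ``alpha``
    and |log2FC| > ``min_abs_log2fc`` are returned with their direction.
    A minimal helper for synthetic-data testing; real analyses may supply
    their own DE table.
    """
    case = expression.loc[labels.index[labels == case_label]]
    ctrl = expression.loc[labels.index[labels == control_label]]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 cells")
    pvals = np.ones(expression.shape[1])
    a, b = case.to_numpy(dtype=float), ctrl.to_numpy(dtype=float)
    for j in range(expression.shape[1]):
        col = np.concatenate([a[:, j], b[:, j]])
        if np.all(col == col[0]):
            continue  # constant gene: p stays 1
        pvals[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    padj = _bh(pvals)
    log2fc = np.log2(a.mean(axis=0) + pseudocount) - np.log2(b.mean(axis=0) + pseudocount)
    table = pd.DataFrame(
        {
            "gene": expression.columns,
            "log2_fold": log2fc,
            "adjusted_p": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    )
    hits = table.loc[(table["adjusted_p"] < alpha) & (table["log2_fold"].abs() > min_abs_log2fc)]
    return hits.reset_index(drop=True)
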