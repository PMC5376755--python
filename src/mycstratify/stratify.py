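"""Unsupervised discovery of MYC-high/MYC-low strata and marker-panel selection.

Samples are clustered over a MYC-target gene panel (Euclidean distance,
complete-linkage agglomeration, cut into two groups); the cluster with greater
mean panel expression is the MYC-high stratum.  Differential expression between
the strata is ranked by Welch's two-sample t statistic on log2 values with
Benjamini-Hochberg false-discovery control, and the 16-gene signature panel is
the 10 top up-ranked MYC-target genes plus the 6 top down-ranked genes from the
whole matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MarkerPanel

__all__ = [
    "resolve_gene_panel",
    "hclust_two_groups",
    "ttest_rank",
    "bh_fdr",
    "select_marker_panel",
    "count_increased",
]

HIGH, LOW = "MYC-high", "MYC-low"


def resolve_gene_panel(expr: ExpressionMatrix, gene_ids) -> tuple[list, list]:
    """Split a user gene list into (resolved, unresolved) against the matrix."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene panel is empty")
    present = set(expr.genes)
    resolved = [g for g in gene_ids if g in present]
    unresolved = [g for g in gene_ids if g not in present]
    return resolved, unresolved


def hclust_two_groups(
    expr: ExpressionMatrix,
    panel_genes,
    return_linkage: bool = False,
):
    """Two-group complete-linkage clustering of samples over a gene panel.

    Distances are Euclidean between samples restricted to ``panel_genes`` on
    the log2 scale.  The agglomerative tree is cut into 2 clusters and the
    cluster with greater mean panel expression is labeled MYC-high.

    Returns a Series mapping sample -> label (and the SciPy linkage matrix if
    ``return_linkage``).
    """
    resolved, unresolved = resolve_gene_panel(expr, panel_genes)
    if unresolved:
        raise KeyError(f"panel genes missing from the expression matrix: {unresolved}")
    log2 = expr.to_log2().subset_genes(resolved).values
    if log2.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")

    points = log2.T.to_numpy(dtype=float)  # samples as points
    dists = pdist(points, metric="euclidean")
    if np.all(dists == 0):
        raise ValueError("all samples identical over the panel; distances degenerate")
    Z = linkage(dists, method="complete")
    assignment = fcluster(Z, t=2, criterion="maxclust")

    means = {c: points[assignment == c].mean() for c in np.unique(assignment)}
    high_cluster = max(means, key=means.get)
    labels = pd.Series(np.where(assignment == high_cluster, HIGH, LOW),
                       index=expr.samples, name="group")
    if return_linkage:
        return labels, Z
    return labels


def ttest_rank(
    expr: ExpressionMatrix,
    labels: pd.Series,
    rank_metric: str = "welch",
) -> pd.DataFrame:
    """Per-gene differential expression between strata, ranked by statistic.

    Welch's two-sample t (default) or a Wilcoxon rank-sum alternative, on log2
    values, high minus low, two-sided p, BH q attached.  Genes with zero
    variance in both groups have an undefined statistic; they are flagged
    (``degenerate``) and ranked last with p = q = 1.

    Returns a DataFrame indexed by gene, sorted by statistic descending, with
    columns ``stat``, ``pvalue``, ``qvalue``, ``mean_diff``, ``direction``,
    ``degenerate``.
    """
    if rank_metric not in ("welch", "wilcoxon"):
        raise ValueError("rank_metric must be 'welch' or 'wilcoxon'")
    labels = labels.loc[expr.samples]
    log2 = expr.to_log2().values
    hi = log2.loc[:, (labels == HIGH).to_numpy()].to_numpy(dtype=float)
    lo = log2.loc[:, (labels == LOW).to_numpy()].to_numpy(dtype=float)
    if hi.shape[1] < 2 or lo.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    mean_diff = hi.mean(axis=1) - lo.mean(axis=1)
    degenerate = (hi.var(axis=1) == 0) & (lo.var(axis=1) == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if rank_metric == "welch":
            stat, pval = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
        else:
            stat = np.empty(log2.shape[0])
            pval = np.empty(log2.shape[0])
            for i in range(log2.shape[0]):
                if degenerate[i]:
                    stat[i], pval[i] = np.nan, np.nan
                    continue
                res = stats.mannwhitneyu(hi[i], lo[i], alternative="two-sided")
                # center U so the sign tracks direction, as a t-like statistic
                stat[i] = res.statistic - hi.shape[1] * lo.shape[1] / 2.0
                pval[i] = res.pvalue

    stat = np.where(degenerate, np.nan, stat)
    pval = np.where(degenerate, 1.0, np.where(np.isnan(pval), 1.0, pval))
    qval = bh_fdr(pval)

    table = pd.DataFrame({
        "stat": stat,
        "pvalue": pval,
        "qvalue": qval,
        "mean_diff": mean_diff,
        "direction": np.where(mean_diff > 0, "up", np.where(mean_diff < 0, "down", "flat")),
        "degenerate": degenerate,
    }, index=expr.genes)
    # NaN statistics (degenerate genes) sort last
    return table.sort_values("stat", ascending=False, na_position="last", kind="mergesort")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{k>=rank(i)} p_(k)*m/k, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return qvals


def select_marker_panel(
    ranked: pd.DataFrame,
    myc_targets,
    n_up: int = 10,
    n_down: int = 6,
) -> MarkerPanel:
    """Build the signature panel from a ranked differential-expression table.

    Up-markers: the ``n_up`` top-ranked genes increased in MYC-high, restricted
    to the MYC-target panel.  Down-markers: the ``n_down`` top-ranked genes
    decreased in MYC-high, drawn from the whole matrix.
    """
    targets = set(myc_targets)
    usable = ranked[~ranked["degenerate"]]

    up_pool = usable[(usable.index.isin(targets)) & (usable["stat"] > 0)]
    up = up_pool.index[:n_up].tolist()
    down_pool = usable[usable["stat"] < 0].sort_values("stat", ascending=True,
                                                       kind="mergesort")
    down = down_pool.index[:n_down].tolist()

    if len(up) < n_up or len(down) < n_down:
        raise ValueError(
            f"not enough marker candidates: {len(up)}/{n_up} up (within targets), "
            f"{len(down)}/{n_down} down"
        )
    return MarkerPanel(up_genes=tuple(up), down_genes=tuple(down))


def count_increased(ranked: pd.DataFrame, myc_targets, q_threshold: float = 0.05) -> int:
    """MYC-target genes with positive mean difference and q below threshold.

    A convenience summary of how much of the target panel moves with the
    strata; the per-gene criterion (mean_diff > 0, q <= threshold) is this
    package's own convention.
    """
    sub = ranked[ranked.index.isin(set(myc_targets))]
    return int(((sub["mean_diff"] > 0) & (sub["qvalue"] <= q_threshold)).sum())
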