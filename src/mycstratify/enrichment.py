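"""Gene set enrichment analysis with phenotype permutation.

Implements the weighted Kolmogorov-Smirnov-like enrichment statistic: genes are
ranked by a differential-expression metric (Welch t by default), a running sum
increments by |metric|^p / sum_set |metric|^p at set members and decrements by
1/(N - |set|) elsewhere, and the enrichment score (ES) is the signed maximum
deviation of that sum.  Significance comes from phenotype-label permutations
with re-ranking: the normalized enrichment score (NES) divides each ES by the
mean |null ES| of matching sign, nominal p uses the add-one same-sign
permutation estimator, and the FDR follows the pooled-NES procedure.

Study defaults: 1,000 permutations, weight p = 1, gene sets kept when their
intersection with the matrix holds 15-500 genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "filter_gene_sets",
    "enrichment_score",
    "tstat_metric",
    "gsea_significance",
]

HIGH, LOW = "MYC-high", "MYC-low"


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect): unique names, nonempty member lists."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list:
        return list(self.sets)


def filter_gene_sets(
    collection: GeneSetCollection,
    matrix_genes,
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect sets with the matrix genes, then keep sizes in [min, max]."""
    present = set(matrix_genes)
    kept, desc = {}, {}
    for name, members in collection.sets.items():
        inter = [g for g in members if g in present]
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
            if name in collection.descriptions:
                desc[name] = collection.descriptions[name]
    if not kept:
        warnings.warn("no gene sets survive size filtering", UserWarning)
    return GeneSetCollection(sets=kept, descriptions=desc)


def enrichment_score(ranked_genes, metric, gene_set, weight: float = 1.0):
    """ES and running-sum profile for one gene set on one ranked list.

    ``ranked_genes`` must be sorted by ``metric`` descending; the set must be
    a proper nonempty subset of the ranked genes.
    """
    ranked_genes = list(ranked_genes)
    metric = np.asarray(metric, dtype=float)
    if len(ranked_genes) != metric.size:
        raise ValueError("ranked_genes and metric lengths differ")
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked_genes), dtype=bool,
                       count=len(ranked_genes))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == metric.size:
        raise ValueError("gene set covers every ranked gene; miss step undefined")

    w = np.abs(metric) ** weight
    denom = w[hits].sum()
    if denom == 0:
        raise ValueError("all set members have zero metric; hit steps undefined")
    steps = np.where(hits, w / denom, -1.0 / (metric.size - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def tstat_metric(X: np.ndarray, high_mask: np.ndarray) -> np.ndarray:
    """Vectorized per-gene Welch t (high minus low) over a genes x samples array."""
    hi = X[:, high_mask]
    lo = X[:, ~high_mask]
    n1, n2 = hi.shape[1], lo.shape[1]
    m1, m2 = hi.mean(axis=1), lo.mean(axis=1)
    v1 = hi.var(axis=1, ddof=1)
    v2 = lo.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se == 0, 0.0, t)


def _batch_es(metric: np.ndarray, membership: np.ndarray, weight: float) -> np.ndarray:
    """ES for all sets at once. membership: sets x genes boolean (gene order fixed)."""
    order = np.argsort(-metric, kind="stable")
    w = np.abs(metric[order]) ** weight
    hits = membership[:, order]                       # sets x genes, ranked order
    sizes = hits.sum(axis=1)
    n = metric.size

    hit_w = hits * w[None, :]
    denom = hit_w.sum(axis=1)
    denom = np.where(denom == 0, np.nan, denom)
    hit_cdf = np.cumsum(hit_w, axis=1) / denom[:, None]
    miss_cdf = np.cumsum(~hits, axis=1) / (n - sizes)[:, None]
    dev = hit_cdf - miss_cdf
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def gsea_significance(
    expr: ExpressionMatrix,
    labels: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Full enrichment report: ES, NES, nominal p and FDR q per gene set.

    Phenotype labels are permuted ``n_perm`` times with full re-ranking of the
    metric.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = labels.loc[expr.samples]
    high_mask = (labels == HIGH).to_numpy()
    if high_mask.sum() < 3 or (~high_mask).sum() < 3:
        raise ValueError("phenotype permutation needs at least 3 samples per group")

    filtered = filter_gene_sets(collection, expr.genes, min_size, max_size)
    set_names = filtered.names()
    if not set_names:
        return pd.DataFrame(columns=["size", "es", "nes", "pvalue", "qvalue"])

    X = expr.to_log2().values.to_numpy(dtype=float)
    genes = list(expr.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((len(set_names), len(genes)), dtype=bool)
    for s, name in enumerate(set_names):
        for g in filtered.sets[name]:
            membership[s, gene_pos[g]] = True
    sizes = membership.sum(axis=1)

    obs_metric = tstat_metric(X, high_mask)
    obs_es = _batch_es(obs_metric, membership, weight)

    rng = np.random.default_rng(seed)
    null_es = np.empty((n_perm, len(set_names)))
    for p in range(n_perm):
        perm_mask = np.zeros_like(high_mask)
        perm_mask[rng.permutation(len(high_mask))[: high_mask.sum()]] = True
        null_es[p] = _batch_es(tstat_metric(X, perm_mask), membership, weight)

    nes = np.full(len(set_names), np.nan)
    pvals = np.ones(len(set_names))
    null_nes = np.full_like(null_es, np.nan)
    for s in range(len(set_names)):
        null_s = null_es[:, s]
        pos = null_s[null_s >= 0]
        neg = null_s[null_s < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        if np.isfinite(pos_mean):
            null_nes[null_s >= 0, s] = null_s[null_s >= 0] / pos_mean
        if np.isfinite(neg_mean):
            null_nes[null_s < 0, s] = null_s[null_s < 0] / neg_mean

        es_s = obs_es[s]
        if es_s >= 0:
            same = pos
            nes[s] = es_s / pos_mean if np.isfinite(pos_mean) else np.nan
            extreme = int((same >= es_s).sum())
        else:
            same = neg
            nes[s] = es_s / neg_mean if np.isfinite(neg_mean) else np.nan
            extreme = int((same <= es_s).sum())
        pvals[s] = (1.0 + extreme) / (1.0 + same.size)

    qvals = _pooled_fdr(nes, null_nes)

    report = pd.DataFrame({
        "size": sizes,
        "es": obs_es,
        "nes": nes,
        "pvalue": pvals,
        "qvalue": qvals,
    }, index=pd.Index(set_names, name="gene_set"))
    return report.sort_values("nes", ascending=False, na_position="last")


def _pooled_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled-NES FDR: tail fraction in the pooled null over tail fraction observed."""
    pooled = null_nes[np.isfinite(null_nes)]
    obs = nes[np.isfinite(nes)]
    q = np.full(nes.shape, np.nan)
    for s, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            null_tail = (pooled >= v).mean() if pooled.size else 1.0
            null_frac = (pooled >= 0).mean() if pooled.size else 1.0
            obs_tail = (obs >= v).mean()
            obs_frac = (obs >= 0).mean()
        else:
            null_tail = (pooled <= v).mean() if pooled.size else 1.0
            null_frac = (pooled < 0).mean() if pooled.size else 1.0
            obs_tail = (obs <= v).mean()
            obs_frac = (obs < 0).mean()
        num = null_tail / null_frac if null_frac > 0 else 1.0
        den = obs_tail / obs_frac if obs_frac > 0 else 1.0
        q[s] = min(1.0, num / den) if den > 0 else 1.0
    return q
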