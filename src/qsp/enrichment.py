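"""Per-sample pathway enrichment and patient clustering.

The single-sample enrichment score follows the gene set variation analysis
scheme: each gene's expression is converted to a cross-sample cumulative
density (kernel-smoothed or empirical), genes are ranked within each
sample, and a weighted Kolmogorov-Smirnov random walk over the ranked list
yields a per-(pathway, sample) enrichment score in [-1, 1]. Patients are
then clustered on standardized enrichment profiles with Ward linkage on
Pearson-correlation distances, the dendrogram is cut to a fixed number of
clusters, and cluster robustness is measured by bootstrap Jaccard
coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("qsp")

__all__ = [
    "ClusterAssignment",
    "single_sample_enrichment",
    "standardize_features",
    "cluster_samples",
    "cluster_stability",
    "association_test",
]


def _kernel_cdf(expr: np.ndarray, kernel: str, chunk: int = 200) -> np.ndarray:
    """Cross-sample CDF estimate per gene (rows) and sample (columns).

    Computed in gene chunks: the pairwise sample-by-sample kernel tensor is
    n_samples^2 per gene and would otherwise dominate memory.
    """
    p = expr.shape[0]
    out = np.empty_like(expr, dtype=float)
    if kernel == "gaussian":
        h = expr.std(axis=1, ddof=1, keepdims=True) / 4.0
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        block = expr[lo:hi]
        if kernel == "gaussian":
            diff = (block[:, :, None] - block[:, None, :]) / h[lo:hi, :, None]
            out[lo:hi] = stats.norm.cdf(diff).mean(axis=2)
        elif kernel == "poisson":
            lam = block[:, None, :] + 0.5
            out[lo:hi] = stats.poisson.cdf(block[:, :, None], lam).mean(axis=2)
        elif kernel == "ecdf":
            out[lo:hi] = (block[:, :, None] >= block[:, None, :]).mean(axis=2)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    return out


def _gsva_walk(order_stat: np.ndarray, in_set: np.ndarray, tau: float, mx_diff: bool) -> float:
    """Weighted KS walk over one sample's ranked gene list.

    ``order_stat``: rank statistic per position, already in walk order
    (highest expression statistic first). ``in_set``: boolean per position.
    """
    p = order_stat.size
    t = int(in_set.sum())
    w = np.abs(order_stat) ** tau * in_set
    denom = w.sum()
    if denom == 0:
        w = in_set.astype(float)
        denom = w.sum()
    walk = np.cumsum(w / denom - (~in_set) / (p - t))
    if mx_diff:
        return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))
    pos, neg = walk.max(), walk.min()
    return float(pos) if pos > -neg else float(neg)


def single_sample_enrichment(
    expr: pd.DataFrame,
    gene_sets,
    kernel: str = "gaussian",
    tau: float = 1.0,
    mx_diff: bool = True,
) -> pd.DataFrame:
    """Pathway x sample enrichment matrix from a gene x sample matrix.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples (>= 2 samples; the CDF is estimated across
        samples). Constant gene rows are excluded with a warning.
    gene_sets : GeneSetCollection or iterable of (name, genes)
        Sets with no member in the gene universe score as missing (NaN).
    kernel : {"gaussian", "poisson", "ecdf"}
        Cross-sample density model: gaussian for log-scale data, poisson
        for counts, ecdf for a plain empirical CDF.
    mx_diff : bool
        True (default): ES = largest positive walk deviation plus largest
        negative deviation (their signed sum, sensitive to bidirectional
        shifts). False: single maximum-deviation variant.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples for cross-sample density estimation")
    const = expr.std(axis=1, ddof=1) == 0
    if const.any():
        warnings.warn(f"excluding {int(const.sum())} constant gene rows from enrichment")
        expr = expr.loc[~const]
    values = expr.to_numpy(dtype=float)
    z = _kernel_cdf(values, kernel)

    p, n = z.shape
    gene_index = {g: i for i, g in enumerate(expr.index)}
    # per sample: order genes by decreasing z; symmetric rank statistic |p/2 - r|
    order = np.argsort(-z, axis=0, kind="mergesort")  # positions -> gene row
    ranks = np.empty_like(order)
    for j in range(n):
        ranks[order[:, j], j] = np.arange(1, p + 1)
    rank_stat = np.abs(p / 2.0 - ranks)

    names, rows = [], []
    for name, members in gene_sets:
        idx = np.array([gene_index[g] for g in set(members) if g in gene_index], dtype=int)
        names.append(name)
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no member in the gene universe")
            rows.append(np.full(n, np.nan))
            continue
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        if in_set.all():
            raise ValueError(f"gene set {name!r} covers the whole universe; walk undefined")
        es = np.empty(n)
        for j in range(n):
            walk_order = order[:, j]
            es[j] = _gsva_walk(
                rank_stat[walk_order, j], in_set[walk_order], tau, mx_diff
            )
        rows.append(es)
    out = pd.DataFrame(np.vstack(rows), index=names, columns=expr.columns)
    out.index.name = "pathway"
    return out


def standardize_features(m: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sample SD 1.

    Constant rows become all-zero (with a warning) so the matrix shape is
    stable for downstream clustering.
    """
    arr = m.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows standardized to zeros")
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=m.index, columns=m.columns)


@dataclass
class ClusterAssignment:
    """Sample -> cluster mapping plus the linkage tree that produced it."""

    labels: pd.Series  # sample id -> cluster label (1..k)
    linkage: np.ndarray
    n_clusters: int

    def members(self, cluster: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster])

    def cluster_ids(self) -> list[int]:
        return sorted(self.labels.unique())


def _correlation_distance(m: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between columns."""
    corr = np.corrcoef(m, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return squareform(d, checks=False)


def cluster_samples(
    m: pd.DataFrame, cut_level: int = 3, standardize: bool = True, method: str = "ward"
) -> ClusterAssignment:
    """Hierarchical clustering of samples on enrichment profiles.

    Distance is 1 - Pearson correlation of (optionally standardized)
    profiles; linkage is Ward applied directly to the distance matrix (the
    Ward.D-on-distances convention). The tree is cut to exactly
    ``cut_level`` clusters.
    """
    if m.shape[1] < cut_level:
        raise ValueError(f"{m.shape[1]} samples < cut level {cut_level}")
    work = standardize_features(m) if standardize else m
    work = work.loc[work.std(axis=1, ddof=0) > 0]
    dist = _correlation_distance(work.to_numpy(dtype=float))
    link = hierarchy.linkage(dist, method=method)
    flat = hierarchy.fcluster(link, t=cut_level, criterion="maxclust")
    labels = pd.Series(flat, index=m.columns, name="cluster")
    return ClusterAssignment(labels=labels, linkage=link, n_clusters=len(set(flat)))


def cluster_stability(
    m: pd.DataFrame,
    assignment: ClusterAssignment,
    n_boot: int = 100,
    seed: int | None = None,
    _resamples=None,
) -> pd.Series:
    """Mean bootstrap Jaccard coefficient per original cluster.

    Each bootstrap resamples the samples with replacement, re-clusters the
    unique drawn samples, and matches every original cluster to its
    maximum-Jaccard counterpart (ties broken by counterpart size, then
    label). Values near 1 indicate stable clusters; below ~0.6 the cluster
    is conventionally considered dissolved.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    samples = list(m.columns)
    n = len(samples)
    k = assignment.n_clusters
    sums = {c: 0.0 for c in assignment.cluster_ids()}
    counts = {c: 0 for c in assignment.cluster_ids()}
    for b in range(n_boot):
        if _resamples is not None:
            idx = np.asarray(_resamples[b])
        else:
            idx = rng.integers(0, n, size=n)
        drawn = sorted({samples[i] for i in idx})
        if len(drawn) < k:
            continue
        sub = cluster_samples(m[drawn], cut_level=k)
        new_clusters = [sub.members(c) for c in sub.cluster_ids()]
        drawn_set = set(drawn)
        for c in assignment.cluster_ids():
            orig = assignment.members(c) & drawn_set
            if not orig:
                continue
            best = 0.0
            for newc in sorted(new_clusters, key=lambda s: (-len(s), sorted(s))):
                j = len(orig & newc) / len(orig | newc)
                if j > best:
                    best = j
            sums[c] += best
            counts[c] += 1
    out = pd.Series(
        {c: (sums[c] / counts[c] if counts[c] else np.nan) for c in assignment.cluster_ids()},
        name="jaccard",
    )
    return out


def association_test(assignment: ClusterAssignment, labels: pd.Series) -> tuple[float, float]:
    """Pearson chi-squared test of cluster membership vs a categorical label.

    No continuity correction. Label categories with zero total count are
    dropped with a warning.
    """
    common = assignment.labels.index.intersection(labels.index)
    table = pd.crosstab(assignment.labels.loc[common], labels.loc[common])
    empty = table.columns[(table.sum(axis=0) == 0)]
    if len(empty):
        warnings.warn(f"dropping empty label categories: {list(empty)}")
        table = table.drop(columns=empty)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p)
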