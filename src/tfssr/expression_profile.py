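"""Differential-expression tagging of marker-associated genes.

FPKM profiles across infection time points are converted to log2 fold
changes against a baseline time point, thresholded into UP/DOWN/FLAT
labels, summarized as Venn-style time-course partitions, and ordered by
agglomerative hierarchical clustering for heat-map export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Non-negative FPKM values, genes x ordered time points."""

    fpkm: pd.DataFrame  # index = gene ids, columns = time points, ordered

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.fpkm.columns.duplicated().any():
            raise ValueError("time point labels must be unique")
        if self.fpkm.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def time_points(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class ClusterResult:
    """Agglomerative clustering output: a scipy-style linkage matrix and
    the dendrogram leaf order (a permutation of the gene ids)."""

    linkage: np.ndarray    # (n-1) x 4: idx_a, idx_b, height, size
    leaf_order: list[str]
    gene_ids: list[str]


def log2_fold_change(em: ExpressionMatrix, baseline_time: str,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """log2((fpkm + c) / (fpkm_baseline + c)) per gene for every
    non-baseline time point."""
    if baseline_time not in em.time_points:
        raise ValueError(f"baseline {baseline_time!r} not among time points")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    base = em.fpkm[baseline_time] + pseudocount
    others = [t for t in em.time_points if t != baseline_time]
    out = {}
    for t in others:
        out[t] = np.log2((em.fpkm[t] + pseudocount) / base)
    return pd.DataFrame(out, index=em.fpkm.index)


def de_classify(log2fc: pd.DataFrame, up_threshold: float = 1.0,
                down_threshold: float = -1.0) -> pd.DataFrame:
    """UP where log2FC >= up_threshold, DOWN where <= down_threshold
    (both inclusive), else FLAT."""
    if not (up_threshold > 0 > down_threshold):
        raise ValueError("need up_threshold > 0 > down_threshold")
    arr = log2fc.to_numpy()
    labels = np.where(arr >= up_threshold, "UP",
                      np.where(arr <= down_threshold, "DOWN", "FLAT"))
    return pd.DataFrame(labels, index=log2fc.index, columns=log2fc.columns)


def time_course_sets(labels: pd.DataFrame, direction: str = "UP"
                     ) -> dict[frozenset, int]:
    """Venn-style partition: for each non-empty subset of time points, the
    number of genes labelled ``direction`` in exactly that subset. The
    all-time-points cell is the intersection count."""
    if direction not in ("UP", "DOWN"):
        raise ValueError("direction must be 'UP' or 'DOWN'")
    out: dict[frozenset, int] = {}
    for gene in labels.index:
        tps = frozenset(t for t in labels.columns
                        if labels.loc[gene, t] == direction)
        if tps:
            out[tps] = out.get(tps, 0) + 1
    return out


def genes_in_all_time_points(labels: pd.DataFrame, direction: str = "UP"
                             ) -> list[str]:
    """Genes carrying ``direction`` at every time point."""
    mask = (labels == direction).all(axis=1)
    return list(labels.index[mask])


# ---------------------------------------------------------------------------
# Hierarchical clustering


def _row_distances(x: np.ndarray, distance: str) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    if distance == "euclidean":
        for i in range(n):
            d[i] = np.sqrt(((x - x[i]) ** 2).sum(axis=1))
    elif distance == "pearson_dissimilarity":
        sd = x.std(axis=1)
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum(axis=1))
        for i in range(n):
            for j in range(i + 1, n):
                if sd[i] == 0 or sd[j] == 0:
                    # zero-variance rows have undefined correlation:
                    # defined as maximally distant
                    dij = 2.0
                else:
                    r = float((xc[i] * xc[j]).sum() / (denom[i] * denom[j]))
                    dij = 1.0 - r
                d[i, j] = d[j, i] = dij
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return d


def hierarchical_cluster(em: ExpressionMatrix, linkage: str = "average",
                         distance: str = "pearson_dissimilarity"
                         ) -> ClusterResult:
    """Agglomerative clustering of log2(FPKM + 1) rows.

    At every step the pair of clusters at minimal distance merges, ties
    broken by the smallest original row index (then the second-smallest);
    inter-cluster distances update by the Lance-Williams rule for the
    chosen linkage. Leaf order lists the cluster containing the smaller
    original index first.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    x = np.log2(em.fpkm.to_numpy(dtype=float) + 1.0)
    n = x.shape[0]
    if n < 2:
        return ClusterResult(np.zeros((0, 4)), list(em.gene_ids), list(em.gene_ids))
    d = _row_distances(x, distance)

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    min_idx = {i: i for i in range(n)}
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    z = np.zeros((n - 1, 4))
    next_id = n

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    for step in range(n - 1):
        ids = sorted(clusters)
        best = None
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = ids[a], ids[b]
                key = (get(i, j), min(min_idx[i], min_idx[j]),
                       max(min_idx[i], min_idx[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _, _), i, j = best
        # put the cluster holding the smaller original index on the left
        if min_idx[j] < min_idx[i]:
            i, j = j, i
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in ids:
            if k in (i, j):
                continue
            dik, djk = get(i, k), get(j, k)
            if linkage == "average":
                dnew = (ni * dik + nj * djk) / (ni + nj)
            elif linkage == "complete":
                dnew = max(dik, djk)
            else:
                dnew = min(dik, djk)
            dist[(min(k, next_id), max(k, next_id))] = dnew
        clusters[next_id] = clusters[i] + clusters[j]
        leaves[next_id] = leaves[i] + leaves[j]
        min_idx[next_id] = min(min_idx[i], min_idx[j])
        z[step] = (i, j, h, ni + nj)
        del clusters[i], clusters[j]
        next_id += 1

    order = leaves[next_id - 1]
    genes = list(em.gene_ids)
    return ClusterResult(z, [genes[i] for i in order], genes)


def heatmap_export(em: ExpressionMatrix, result: ClusterResult) -> pd.DataFrame:
    """log2(FPKM + 1) values in dendrogram leaf order (heat-map input)."""
    log = np.log2(em.fpkm + 1.0)
    return log.loc[result.leaf_order]
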