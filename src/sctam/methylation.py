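"""Binarized methylation analysis: distances, Ward clustering, enrichment.

A cell's methylation call for an amplicon is 1 iff at least one read maps to
it — justified by the sub-percent digestion-failure rate, which makes any
read in the digested sample strong evidence of a methylated (undigested)
site.  Cells (and CpGs) are compared with the asymmetric binary distance —
the fraction of discordant calls among positions where at least one of the
two vectors is methylated — and grouped by Ward's minimum-variance method
(ward.D2 semantics: the Lance-Williams recurrence on squared
dissimilarities) on that distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import CountMatrix

__all__ = [
    "BinaryMethylationMatrix",
    "ClusterAssignment",
    "binarize",
    "binary_distance",
    "binary_distance_matrix",
    "ward_cluster",
    "cluster_cells",
    "cluster_cpgs",
    "cluster_mean_methylation",
    "fisher_state_enrichment",
    "meth_expression_correlation",
    "silhouette_report",
]


@dataclass
class BinaryMethylationMatrix:
    """Cells x amplicons methylation calls in {0, 1}."""

    calls: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        v = self.calls.to_numpy()
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("calls must be binary")
        self.calls = self.calls.astype(np.int8)

    @property
    def cells(self) -> list[str]:
        return list(self.calls.index)

    @property
    def amplicons(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class ClusterAssignment:
    """Flat cluster labels (1..k) plus the linkage merge history."""

    labels: pd.Series
    linkage: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        heights = self.linkage[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def binarize(counts: CountMatrix, amplicon_subset=None) -> BinaryMethylationMatrix:
    """Call methylated (1) iff an amplicon has >= 1 read in a cell."""
    sub = counts if amplicon_subset is None else counts.subset_amplicons(amplicon_subset)
    calls = pd.DataFrame(
        (sub.counts >= 1).astype(np.int8), index=sub.barcodes, columns=sub.amplicons
    )
    return BinaryMethylationMatrix(calls, source=f"{counts.condition} counts")


def binary_distance(a, b) -> float:
    """Asymmetric binary (Jaccard) distance between two 0/1 vectors.

    d = (n10 + n01) / (n11 + n10 + n01); joint absences are ignored and
    d = 0 when the denominator is zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    denom = int(np.logical_or(a, b).sum())
    if denom == 0:
        return 0.0
    return float(np.logical_xor(a, b).sum() / denom)


def binary_distance_matrix(matrix: BinaryMethylationMatrix) -> np.ndarray:
    """Condensed pairwise binary distance over rows (cells)."""
    x = matrix.calls.to_numpy(dtype=bool)
    # vectorized Jaccard: |xor| / |or| per pair, both-zero pairs -> 0
    inter = x.astype(np.int32) @ x.T.astype(np.int32)
    ones = x.sum(axis=1).astype(np.int32)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - inter) / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def ward_cluster(distance, k: int) -> ClusterAssignment:
    """Ward agglomeration of a precomputed dissimilarity, cut at ``k`` groups.

    ``distance`` is a square symmetric zero-diagonal matrix (optionally a
    pandas DataFrame carrying item ids) or a condensed vector.  Uses the
    ward.D2 update (Lance-Williams on squared dissimilarities); labels are
    renumbered 1..k in order of first appearance.
    """
    ids = None
    if isinstance(distance, pd.DataFrame):
        ids = list(distance.index)
        distance = distance.to_numpy()
    distance = np.asarray(distance, dtype=float)
    if distance.ndim == 2:
        if distance.shape[0] != distance.shape[1] or not np.allclose(distance, distance.T):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(distance), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        n = distance.shape[0]
        condensed = squareform(distance, checks=False)
    else:
        condensed = distance
        n = int(round((1 + np.sqrt(1 + 8 * condensed.size)) / 2))
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if ids is None:
        ids = list(range(n))
    if n == 1:
        return ClusterAssignment(pd.Series([1], index=ids), np.empty((0, 4)), k)
    link = hierarchy.linkage(condensed, method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # renumber clusters 1..k by first appearance for determinism
    order: dict[int, int] = {}
    labels = []
    for r in raw:
        order.setdefault(r, len(order) + 1)
        labels.append(order[r])
    return ClusterAssignment(pd.Series(labels, index=ids), link, k)


def cluster_cells(matrix: BinaryMethylationMatrix, k: int) -> ClusterAssignment:
    """Ward clustering of cells on the binary distance."""
    cond = binary_distance_matrix(matrix)
    assign = ward_cluster(cond, k)
    assign.labels.index = matrix.cells
    return assign


def cluster_cpgs(matrix: BinaryMethylationMatrix, k: int) -> ClusterAssignment:
    """Ward clustering of amplicons (columns) on the binary distance."""
    t = BinaryMethylationMatrix(matrix.calls.T, source=matrix.source + " (transposed)")
    assign = ward_cluster(binary_distance_matrix(t), k)
    assign.labels.index = matrix.amplicons
    return assign


def cluster_mean_methylation(
    matrix: BinaryMethylationMatrix,
    cell_clusters: ClusterAssignment,
    cpg_clusters: ClusterAssignment,
) -> pd.DataFrame:
    """Mean methylation +/- 2 SE per (cell cluster, CpG cluster) block.

    SE uses the binomial form sqrt(p(1-p)/n_cells) — cells, not calls, are
    the sampling unit.
    """
    rows = []
    for cc in range(1, cell_clusters.k + 1):
        cells = cell_clusters.members(cc)
        for pc in range(1, cpg_clusters.k + 1):
            cpgs = cpg_clusters.members(pc)
            if not cells or not cpgs:
                rows.append({"cell_cluster": cc, "cpg_cluster": pc, "mean": np.nan,
                             "se": np.nan, "n_cells": len(cells), "empty": True})
                continue
            block = matrix.calls.loc[cells, cpgs].to_numpy()
            p = float(block.mean())
            se = float(np.sqrt(p * (1 - p) / len(cells)))
            rows.append({"cell_cluster": cc, "cpg_cluster": pc, "mean": p,
                         "se": se, "n_cells": len(cells), "empty": False})
    out = pd.DataFrame(rows)
    out["ci_low"] = out["mean"] - 2 * out["se"]
    out["ci_high"] = out["mean"] + 2 * out["se"]
    return out


def fisher_state_enrichment(
    cluster_ids,
    background_ids,
    states: pd.Series,
    state_of_interest: str,
) -> dict:
    """Enrichment of a chromatin state in a CpG cluster vs the background.

    Two-sided Fisher exact test on the 2x2 table (in cluster vs rest) x
    (state vs other); the sample odds ratio is reported.  Degenerate margins
    yield p = 1 with a warning flag.
    """
    cluster = set(cluster_ids)
    background = list(background_ids)
    if not cluster <= set(background):
        raise ValueError("cluster must be a subset of the background")
    states = pd.Series(states)
    missing = [c for c in background if c not in states.index]
    if missing:
        raise ValueError(f"no chromatin state for: {missing[:5]}")
    in_state = states.reindex(background) == state_of_interest
    in_clust = pd.Index(background).isin(cluster)
    a = int((in_state & in_clust).sum())
    b = int((~in_state & in_clust).sum())
    c = int((in_state & ~in_clust).sum())
    d = int((~in_state & ~in_clust).sum())
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return {"odds_ratio": np.nan, "p_value": 1.0, "table": [[a, b], [c, d]],
                "degenerate": True}
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {"odds_ratio": float(odds), "p_value": float(res.pvalue),
            "table": [[a, b], [c, d]], "degenerate": False}


def meth_expression_correlation(
    pseudobulk_meth: pd.DataFrame,
    expression: pd.DataFrame,
    gene_coords: pd.DataFrame,
    cpg_coords: pd.DataFrame,
    window: int = 25_000,
) -> pd.DataFrame:
    """Correlate per-cluster methylation with expression of nearby genes.

    For every CpG, genes whose body interval lies within ``window`` bp on
    either side (distance from the CpG position to the [start, end) interval,
    same chromosome) are candidates; Pearson r is computed across the shared
    cluster columns.  ``gene_coords`` needs columns chrom/start/end,
    ``cpg_coords`` columns chrom/pos (0-based).
    """
    shared = [c for c in pseudobulk_meth.columns if c in expression.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared clusters")
    rows = []
    for cpg in pseudobulk_meth.index:
        if cpg not in cpg_coords.index:
            continue
        chrom, pos = cpg_coords.loc[cpg, "chrom"], int(cpg_coords.loc[cpg, "pos"])
        for gene in expression.index:
            if gene not in gene_coords.index:
                continue
            g = gene_coords.loc[gene]
            if g["chrom"] != chrom:
                continue
            if pos >= int(g["end"]):
                dist = pos - (int(g["end"]) - 1)
            elif pos < int(g["start"]):
                dist = int(g["start"]) - pos
            else:
                dist = 0
            if dist > window:
                continue
            m = pseudobulk_meth.loc[cpg, shared].to_numpy(dtype=float)
            e = expression.loc[gene, shared].to_numpy(dtype=float)
            if np.std(m) == 0 or np.std(e) == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(m, e).statistic)
            rows.append({"cpg": cpg, "gene": gene, "r": r, "distance_bp": dist})
    out = pd.DataFrame(rows, columns=["cpg", "gene", "r", "distance_bp"])
    return out.sort_values("r", key=np.abs, ascending=False, ignore_index=True)


def silhouette_report(matrix: BinaryMethylationMatrix, k_range=range(2, 9)) -> pd.DataFrame:
    """Mean silhouette width of the Ward partition over a range of k.

    Emitted as an aid for choosing k; no automatic selection is performed.
    """
    from sklearn.metrics import silhouette_score

    square = squareform(binary_distance_matrix(matrix))
    rows = []
    for k in k_range:
        if k >= len(matrix.cells):
            break
        labels = cluster_cells(matrix, k).labels.to_numpy()
        rows.append({"k": k, "mean_silhouette":
                     float(silhouette_score(square, labels, metric="precomputed"))})
    return pd.DataFrame(rows)
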