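"""Analytics on the reconstructed SMN graph.

Spatial relationships among query cells are read off the graph, not off
coordinates: the SMN distance between two cells is the unweighted
shortest-path length, and the distance from a cell to a cell group is the
mean SMN distance to the k nearest group members. Spatial neighborhoods are
clusters of cells by the accumulated expression of their first-degree SMNs
(microenvironment rather than intrinsic state), with the cluster count
chosen by the silhouette coefficient. Composition and enrichment tools
quantify which cell types surround which, and spatial gradients order cells
by group distance to trace expression change across the tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .smn import SMNGraph

logger = logging.getLogger(__name__)


@dataclass
class GroupDistanceResult:
    """Per-cell mean SMN distance to the k nearest members of a group."""

    values: pd.Series  # index: cell id, value: D(x, A), may be +inf
    group_label: str
    k_used: int


@dataclass
class SpatialNeighborhoods:
    labels: pd.Series  # cell id -> neighborhood id (0-based)
    K: int
    accumulated_expr: pd.DataFrame  # cells x genes
    markers: dict[int, pd.DataFrame]
    sc_markers: dict[int, pd.DataFrame] | None = None
    silhouette_by_k: dict[int, float] | None = None


@dataclass
class CompositionTable:
    """SMN composition fractions (query type x neighbor type)."""

    fractions: pd.DataFrame
    counts: pd.DataFrame


def _adjacency(graph: SMNGraph) -> tuple[scipy.sparse.csr_matrix, dict[str, int]]:
    index = {n: i for i, n in enumerate(graph.node_ids)}
    rows, cols = [], []
    for e in graph.edges:
        a, b = tuple(e)
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    n = len(graph.node_ids)
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return adj, index


def graph_distance_matrix(graph: SMNGraph) -> pd.DataFrame:
    """All-pairs SMN distances (BFS); unreachable pairs are +inf."""
    adj, _ = _adjacency(graph)
    D = shortest_path(adj, method="D", unweighted=True, directed=False)
    return pd.DataFrame(D, index=graph.node_ids, columns=graph.node_ids)


def smn_distance(graph: SMNGraph, a: str, b: str) -> float:
    """Unweighted shortest-path length between two cells (inf if unreachable)."""
    adj, index = _adjacency(graph)
    for node in (a, b):
        if node not in index:
            raise KeyError(f"unknown node {node!r}")
    if a == b:
        return 0.0
    dist = shortest_path(
        adj, method="D", unweighted=True, directed=False, indices=index[a]
    )
    return float(dist[index[b]])


def distance_to_group(graph: SMNGraph, x: str, A: set[str] | list[str], k: int = 30) -> float:
    """Mean SMN distance from x to the k nearest members of group A.

    Unreachable members are excluded before taking the nearest k; with fewer
    than k reachable members all of them are used; with none, +inf.
    """
    members = list(A)
    if not members:
        raise ValueError("group A must be nonempty")
    adj, index = _adjacency(graph)
    if x not in index:
        raise KeyError(f"unknown node {x!r}")
    for m in members:
        if m not in index:
            raise KeyError(f"unknown group member {m!r}")
    dist = shortest_path(
        adj, method="D", unweighted=True, directed=False, indices=index[x]
    )
    d = np.sort(dist[[index[m] for m in members]])
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("inf")
    return float(d[: min(k, d.size)].mean())


def group_distance_profile(
    graph: SMNGraph, A: set[str] | list[str], k: int = 30, label: str = ""
) -> GroupDistanceResult:
    """D(x, A) for every cell x of the graph, computed with batched BFS."""
    members = list(A)
    if not members:
        raise ValueError("group A must be nonempty")
    adj, index = _adjacency(graph)
    missing = [m for m in members if m not in index]
    if missing:
        raise KeyError(f"unknown group members: {missing[:5]}")
    rows = [index[m] for m in members]
    # BFS from each group member: |A| x n distances
    D = shortest_path(adj, method="D", unweighted=True, directed=False, indices=rows)
    D = np.sort(D, axis=0)
    k_used = min(k, len(members))
    values = np.empty(len(graph.node_ids))
    for j in range(D.shape[1]):
        col = D[:, j]
        finite = col[np.isfinite(col)]
        values[j] = finite[: min(k, finite.size)].mean() if finite.size else np.inf
    return GroupDistanceResult(
        values=pd.Series(values, index=graph.node_ids),
        group_label=label,
        k_used=k_used,
    )


def accumulate_smn_expression(expr: ExpressionMatrix, graph: SMNGraph) -> pd.DataFrame:
    """Summed raw counts of each cell's first-degree SMNs (cells x genes).

    The cell itself is excluded; zero-degree cells get zero rows with a
    warning.
    """
    missing = [n for n in graph.node_ids if n not in set(expr.obs_ids)]
    if missing:
        raise KeyError(f"graph nodes missing from expression: {missing[:5]}")
    adj, _ = _adjacency(graph)
    col_of = {o: j for j, o in enumerate(expr.obs_ids)}
    counts = expr.counts[:, [col_of[n] for n in graph.node_ids]]  # genes x nodes
    accumulated = adj @ counts.T  # nodes x genes
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(degrees == 0):
        logger.warning(
            "%d isolated cells have zero accumulated expression",
            int((degrees == 0).sum()),
        )
    return pd.DataFrame(
        np.asarray(accumulated), index=graph.node_ids, columns=expr.gene_ids
    )


def _normalize_accumulated(acc: np.ndarray) -> np.ndarray:
    """Median-library-size normalize rows, log1p, per-gene (column) z-scale."""
    totals = acc.sum(axis=1)
    median_total = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    safe = np.where(totals == 0, 1.0, totals)
    norm = np.log1p(acc / safe[:, None] * median_total)
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (norm - mu) / sd


def marker_genes(matrix: pd.DataFrame, labels: pd.Series, alpha_sort: bool = False) -> dict[int, pd.DataFrame]:
    """One-vs-rest rank-sum markers per cluster, BH-adjusted within cluster.

    ``matrix`` is cells x genes (raw or accumulated counts); log-fold-change
    is computed on library-normalized log1p values.
    """
    totals = matrix.to_numpy().sum(axis=1)
    safe = np.where(totals == 0, 1.0, totals)
    norm = np.log1p(matrix.to_numpy() / safe[:, None] * 1e4)
    out: dict[int, pd.DataFrame] = {}
    for cluster in sorted(labels.unique()):
        in_mask = (labels == cluster).to_numpy()
        stats, pvals = ranksums(norm[in_mask], norm[~in_mask], axis=0)
        lfc = norm[in_mask].mean(axis=0) - norm[~in_mask].mean(axis=0)
        pvals = np.nan_to_num(pvals, nan=1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "gene": matrix.columns,
                "log_fold_change": lfc,
                "statistic": stats,
                "pvalue": pvals,
                "padj": padj,
            }
        ).sort_values(["padj", "pvalue", "gene"], kind="stable")
        out[int(cluster)] = df.reset_index(drop=True)
    return out


def find_spatial_neighborhood(
    accumulated: pd.DataFrame,
    K_range: range | list[int] = range(2, 9),
    seed: int = 60611,
    sc_expr: pd.DataFrame | None = None,
) -> SpatialNeighborhoods:
    """Cluster cells by accumulated SMN expression into spatial neighborhoods.

    Normalizes counts (median library size, log1p, per-gene z-scale), runs
    PCA to 32 (or rank) components, and for each candidate K runs seeded
    K-means (10 restarts), choosing the K with the highest mean silhouette
    (ties toward smaller K). Markers are one-vs-rest rank-sum tests,
    BH-adjusted, on the accumulated matrix and, if given, on single-cell
    expression.
    """
    K_range = sorted(K_range)
    X = accumulated.to_numpy(dtype=float)
    if X.shape[0] < max(K_range) + 1:
        raise ValueError("need more cells than the largest candidate K")
    Z = _normalize_accumulated(X)
    if np.allclose(Z, 0):
        raise ValueError("all cells identical after normalization")
    n_comp = min(32, min(Z.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(Z)

    sil_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for K in K_range:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        lab = km.fit_predict(pcs)
        labels_by_k[K] = lab
        if len(np.unique(lab)) < 2:
            sil_by_k[K] = -1.0
        else:
            sil_by_k[K] = float(silhouette_score(pcs, lab))
    best_K = max(K_range, key=lambda K: (sil_by_k[K], -K))
    labels = pd.Series(labels_by_k[best_K], index=accumulated.index)

    markers = marker_genes(accumulated, labels)
    sc_markers = None
    if sc_expr is not None:
        sc_markers = marker_genes(sc_expr.loc[accumulated.index], labels)
    return SpatialNeighborhoods(
        labels=labels,
        K=best_K,
        accumulated_expr=accumulated,
        markers=markers,
        sc_markers=sc_markers,
        silhouette_by_k=sil_by_k,
    )


def neighbor_composition(graph: SMNGraph, annotations: dict[str, str]) -> CompositionTable:
    """Pool the SMNs of each query type and tabulate neighbor-type fractions."""
    unannotated = [n for n in graph.node_ids if n not in annotations]
    if unannotated:
        raise ValueError(f"unannotated nodes: {unannotated[:5]}")
    types = sorted(set(annotations[n] for n in graph.node_ids))
    counts = pd.DataFrame(0, index=types, columns=types, dtype=float)
    for e in graph.edges:
        a, b = tuple(e)
        counts.loc[annotations[a], annotations[b]] += 1
        counts.loc[annotations[b], annotations[a]] += 1
    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return CompositionTable(fractions=fractions, counts=counts)


def neighbor_enrichment_test(
    graph: SMNGraph, annotations: dict[str, str], query_type: str
) -> pd.DataFrame:
    """Which neighbor types are enriched around cells of ``query_type``.

    For each neighbor type, the per-cell count of neighbors of that type is
    compared between query cells and all other cells with a two-sided
    rank-sum test; p-values are BH-adjusted across neighbor types.
    """
    unannotated = [n for n in graph.node_ids if n not in annotations]
    if unannotated:
        raise ValueError(f"unannotated nodes: {unannotated[:5]}")
    query_cells = [n for n in graph.node_ids if annotations[n] == query_type]
    if len(query_cells) < 2:
        raise ValueError(f"need >= 2 cells of type {query_type!r}")
    types = sorted(set(annotations[n] for n in graph.node_ids))
    neighbor_counts = pd.DataFrame(0, index=graph.node_ids, columns=types, dtype=float)
    for e in graph.edges:
        a, b = tuple(e)
        neighbor_counts.loc[a, annotations[b]] += 1
        neighbor_counts.loc[b, annotations[a]] += 1
    is_query = np.array([annotations[n] == query_type for n in graph.node_ids])
    rows = []
    for t in types:
        x = neighbor_counts[t].to_numpy()[is_query]
        y = neighbor_counts[t].to_numpy()[~is_query]
        if np.all(x == x[0]) and len(y) and np.all(y == x[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = ranksums(x, y)
            if np.isnan(p):
                p = 1.0
        rows.append({"neighbor_type": t, "statistic": stat, "pvalue": p})
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["padj", "pvalue"], kind="stable").reset_index(drop=True)


def spatial_gradient(
    graph: SMNGraph,
    expr: ExpressionMatrix,
    reference_group: set[str] | list[str],
    genes: list[str],
    k: int = 30,
    window: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Order cells by SMN distance to a reference group and trace expression.

    Returns (ordered expression trace with optional rolling-mean smoothing,
    ordered distance vector). Ties in distance break by cell order.
    """
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(f"genes absent from expression: {missing}")
    profile = group_distance_profile(graph, reference_group, k=k)
    dist = profile.values
    order = dist.reset_index(drop=True).sort_values(kind="stable").index
    ordered_cells = [graph.node_ids[i] for i in order]
    gene_rows = {g: i for i, g in enumerate(expr.gene_ids)}
    col_of = {o: j for j, o in enumerate(expr.obs_ids)}
    data = {
        g: expr.counts[gene_rows[g], [col_of[c] for c in ordered_cells]] for g in genes
    }
    trace = pd.DataFrame(data, index=ordered_cells)
    if window and window > 1:
        trace = trace.rolling(window=window, min_periods=1).mean()
    return trace, dist.loc[ordered_cells]
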