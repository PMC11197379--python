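"""Reconstruction-quality metrics.

Two complementary measures compare a reconstruction against ground truth.
The per-cell K-L divergence compares a cell's *spatial distribution* -- its
pairwise-distance row normalized to sum to one, P_ij = D_ij / sum_j D_ij --
between prediction and truth, capturing global placement quality. The mean
neighborhood cosine similarity compares the accumulated transcriptome of a
cell's k nearest predicted neighbors against that of its k nearest
ground-truth neighbors (k swept 3..15), capturing local neighborhood
recapitulation. Natural log is used for KL; ground-truth denominators are
floored at 1e-12 and zero numerator terms contribute zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class SpatialDistribution:
    """Row-stochastic matrix of normalized pairwise distances."""

    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.P < 0):
            raise ValueError("spatial distribution entries must be nonnegative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("spatial distribution rows must sum to 1")


@dataclass
class BenchmarkReport:
    kl_per_cell: np.ndarray
    cosine_by_k: dict[int, float]
    baseline_kl_per_cell: np.ndarray | None = None
    baseline_cosine_by_k: dict[int, float] | None = None


def spatial_distribution(dist: np.ndarray) -> SpatialDistribution:
    """Normalize each cell's distance row to a probability distribution."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance diagonal must be zero")
    sums = D.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("a cell has zero distance to every other cell")
    return SpatialDistribution(P=D / sums[:, None])


def kl_divergence_per_cell(a: SpatialDistribution, b: SpatialDistribution) -> np.ndarray:
    """KL(a_i || b_i) per cell, natural log.

    Terms with a_ij = 0 contribute zero; b entries are floored at 1e-12
    before the ratio so prediction mass on truth-zero positions is penalized
    finitely.
    """
    if a.P.shape != b.P.shape:
        raise ValueError("distributions must have the same shape")
    pa = a.P
    pb = np.maximum(b.P, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pa > 0, pa * np.log(pa / pb), 0.0)
    return terms.sum(axis=1)


def _nearest_lists_from_coords(coords: np.ndarray, k_max: int) -> np.ndarray:
    """For each row, indices of the k_max nearest other rows (ascending)."""
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k_max]


def neighborhood_cosine_similarity(
    pred_neighbors: list[list[int]] | np.ndarray,
    truth_coords: np.ndarray,
    counts: np.ndarray,
    k_range: range | list[int] = range(3, 16),
) -> dict[int, float]:
    """Mean cosine similarity between predicted and true neighborhood profiles.

    ``pred_neighbors[i]`` ranks cell i's predicted neighbors, nearest first;
    ``counts`` is genes x cells (raw). For each k and cell, the accumulated
    count vectors of the k nearest predicted and k nearest ground-truth
    (Euclidean on ``truth_coords``) neighbors are compared by cosine; the
    per-k mean over cells is reported. Cells whose accumulated vector is
    zero are skipped with a warning.
    """
    k_range = sorted(k_range)
    k_max = max(k_range)
    counts = np.asarray(counts, dtype=float)
    c = counts.shape[1]
    if truth_coords.shape[0] != c:
        raise ValueError("truth coords and counts disagree on cell count")
    for i, lst in enumerate(pred_neighbors):
        if len(lst) < k_max:
            raise ValueError(
                f"cell {i} has {len(lst)} predicted neighbors; need >= {k_max}"
            )
    true_nb = _nearest_lists_from_coords(truth_coords, k_max)

    out: dict[int, float] = {}
    skipped = 0
    for k in k_range:
        sims = []
        for i in range(c):
            A = counts[:, list(pred_neighbors[i][:k])].sum(axis=1)
            B = counts[:, true_nb[i, :k]].sum(axis=1)
            na, nb = np.linalg.norm(A), np.linalg.norm(B)
            if na == 0 or nb == 0:
                skipped += 1
                continue
            sims.append(float(A @ B / (na * nb)))
        out[k] = float(np.mean(sims)) if sims else float("nan")
    if skipped:
        logger.warning("skipped %d zero-accumulation cells across k values", skipped)
    return out


def predicted_neighbor_ranking(
    graph_distances: np.ndarray, affinity: np.ndarray | None = None
) -> list[list[int]]:
    """Rank every cell's neighbors by SMN graph distance (ties by affinity).

    ``graph_distances`` is the all-pairs SMN distance matrix (inf allowed);
    higher affinity breaks ties toward the front. Self is excluded.
    """
    c = graph_distances.shape[0]
    out = []
    for i in range(c):
        d = graph_distances[i].copy()
        d[i] = np.inf
        if affinity is not None:
            keys = np.lexsort((-affinity[i], d))
        else:
            keys = np.argsort(d, kind="stable")
        out.append([j for j in keys if j != i])
    return out


def finite_graph_distances(graph_distances: np.ndarray) -> np.ndarray:
    """Replace +inf (unreachable) entries with max finite distance + 1."""
    D = np.array(graph_distances, dtype=float)
    finite = D[np.isfinite(D)]
    if finite.size == 0:
        raise ValueError("no finite distances in the graph")
    cap = finite.max() + 1.0
    D[~np.isfinite(D)] = cap
    np.fill_diagonal(D, 0.0)
    return D
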