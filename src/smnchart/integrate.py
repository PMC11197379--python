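"""Joint embedding of the ST reference and the SC query.

The transcriptome-to-space model is trained on reference pixels but applied
to query cells, so both must live in one expression space. The default is a
diagonal CCA computed by SVD of the cross-product of the two z-scaled
expression matrices over shared highly variable genes -- the classic
reference/query integration geometry -- with ``pca_concat`` (PCA of the
row-concatenated data) available as an ablation. Embedding rows are
L2-normalized so downstream distances are cosine-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, QueryCells, SpatialTranscriptome

logger = logging.getLogger(__name__)


@dataclass
class JointEmbedding:
    """Aligned low-dimensional representations of pixels and cells."""

    X_st: np.ndarray  # pixels x q
    Y_sc: np.ndarray  # cells x q
    genes_used: list[str]
    method_tag: str

    def __post_init__(self) -> None:
        if self.X_st.shape[1] != self.Y_sc.shape[1]:
            raise ValueError("X_st and Y_sc must share the embedding width")
        if not (np.all(np.isfinite(self.X_st)) and np.all(np.isfinite(self.Y_sc))):
            raise ValueError("embedding contains non-finite values")


def _libnorm_log(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    """Library-size normalize columns (observations) to `target`, then log1p."""
    totals = counts.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(counts / totals * target)


def _normalized_dispersion(counts: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-flavor per-gene dispersion, z-scored within mean-expression bins."""
    norm = counts / np.where(counts.sum(axis=0) == 0, 1.0, counts.sum(axis=0)) * 1e4
    mean = norm.mean(axis=1)
    var = norm.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # bin genes by mean expression, standardize dispersion within each bin
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for idx in bins:
        if len(idx) == 0:
            continue
        d = disp[idx]
        sd = d.std()
        z[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    return z


def _zscale_genes(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows (genes); returns (scaled, keep-mask of non-constant genes)."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    keep = (sd[:, 0] > 0)
    scaled = np.zeros_like(mat)
    scaled[keep] = (mat[keep] - mu[keep]) / sd[keep]
    return scaled, keep


def _canonical_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip singular-vector pairs so each U column's largest-|entry| is positive."""
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return U, V


def _l2_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    return mat / norms


def joint_embed(
    st: SpatialTranscriptome,
    sc: QueryCells,
    q: int = 32,
    n_hvg: int = 2000,
    method: str = "cca_svd",
) -> JointEmbedding:
    """Embed ST pixels and SC cells into a shared q-dimensional space.

    Pipeline: library-size normalize to 1e4 and log1p each dataset; select
    up to ``n_hvg`` shared genes by normalized dispersion on the reference
    (the reference defines the spatial signal); z-scale per gene within each
    dataset; then either SVD of the cross-product (``cca_svd``, default) or
    PCA of the concatenated rows (``pca_concat``). Rows are L2-normalized.
    Deterministic: no randomized solvers.
    """
    st_expr, sc_expr = st.expr, sc.expr
    shared = [g for g in st_expr.gene_ids if g in set(sc_expr.gene_ids)]
    if len(shared) < q + 1:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least q+1 = {q + 1}"
        )
    st_idx = {g: i for i, g in enumerate(st_expr.gene_ids)}
    sc_idx = {g: i for i, g in enumerate(sc_expr.gene_ids)}

    st_counts = st_expr.counts[[st_idx[g] for g in shared]]
    sc_counts = sc_expr.counts[[sc_idx[g] for g in shared]]

    # HVG by dispersion on the ST reference
    z_disp = _normalized_dispersion(st_counts)
    n_take = min(n_hvg, len(shared))
    hvg_order = np.argsort(-z_disp, kind="stable")[:n_take]
    hvg_order = np.sort(hvg_order)
    genes_used = [shared[i] for i in hvg_order]

    A = _zscale_genes(_libnorm_log(st_counts[hvg_order]))
    B = _zscale_genes(_libnorm_log(sc_counts[hvg_order]))
    keep = A[1] & B[1]
    if not np.all(keep):
        logger.warning("dropping %d constant gene columns", int((~keep).sum()))
    Z_st, Z_sc = A[0][keep], B[0][keep]
    genes_used = [g for g, k in zip(genes_used, keep) if k]
    if len(genes_used) < q + 1:
        raise ValueError("too few non-constant shared genes for the embedding")

    p, c = Z_st.shape[1], Z_sc.shape[1]
    q_eff = min(q, p, c)
    if q_eff < q:
        logger.warning("embedding truncated to %d dimensions", q_eff)

    if method == "cca_svd":
        K = Z_st.T @ Z_sc  # pixels x cells cross-product over shared HVGs
        U, s, Vt = np.linalg.svd(K, full_matrices=False)
        U, V = _canonical_signs(U[:, :q_eff], Vt.T[:, :q_eff])
        X_st, Y_sc = _l2_rows(U), _l2_rows(V)
    elif method == "pca_concat":
        combined = np.vstack([Z_st.T, Z_sc.T])
        centered = combined - combined.mean(axis=0, keepdims=True)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        scores = U[:, :q_eff] * s[:q_eff]
        # reuse the CCA sign convention for reproducibility
        scores, _ = _canonical_signs(scores, scores.copy())
        X_st, Y_sc = _l2_rows(scores[:p]), _l2_rows(scores[p:])
    else:
        raise ValueError(f"unknown integration method {method!r}")

    return JointEmbedding(
        X_st=X_st, Y_sc=Y_sc, genes_used=genes_used, method_tag=method
    )
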