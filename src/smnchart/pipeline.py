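"""End-to-end reconstruction: ST reference + SC query -> SMN graph.

Chains the stages in order: joint embedding, spatial-information components
of the reference, ensemble transcriptome-to-space training, learning-
variance filtering, stable-matching neighbor assignment, and (optionally)
the 3D layout. Every stage draws its randomness from the single pipeline
seed, so a rerun with the same inputs and seed is bitwise identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .integrate import JointEmbedding, joint_embed
from .io import QueryCells, SpatialTranscriptome
from .sic import SICBasis, compute_sics, pairwise_pixel_distance, shift_nonnegative
from .smn import Layout3D, SMNGraph, assign_smn_graph, layout_3d
from .t2s import EnsembleAffinity, filter_high_variance_cells, run_ensemble

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    embedding: JointEmbedding
    sic_basis: SICBasis
    ensemble: EnsembleAffinity
    graph: SMNGraph
    layout: Layout3D | None
    kept_cell_ids: list[str]
    config: PipelineConfig


def reconstruct(
    st: SpatialTranscriptome,
    sc: QueryCells,
    config: PipelineConfig | None = None,
    compute_layout: bool = True,
) -> ReconstructionResult:
    """Reconstruct the single-cell spatial neighborhood graph."""
    cfg = config or PipelineConfig()

    logger.info("integrating %d pixels with %d cells", st.expr.n_obs, sc.expr.n_obs)
    emb = joint_embed(st, sc, q=cfg.q, n_hvg=cfg.n_hvg)

    logger.info("computing spatial-information components (d=%d)", cfg.d)
    D = pairwise_pixel_distance(st.coords)
    basis = shift_nonnegative(compute_sics(D, d=cfg.d))

    logger.info("training %d-run T2S ensemble", cfg.n_runs)
    ens = run_ensemble(
        emb.X_st,
        basis.scores,
        emb.Y_sc,
        config=cfg.t2s,
        n_runs=cfg.n_runs,
        base_seed=cfg.seed,
    )
    ens = filter_high_variance_cells(ens)
    kept_ids = [sc.expr.obs_ids[i] for i in ens.kept_cells]
    n_dropped = sc.expr.n_obs - len(kept_ids)
    if n_dropped:
        logger.info("variance filter removed %d of %d cells", n_dropped, sc.expr.n_obs)

    logger.info("assigning %d stable-matching neighbors per cell", cfg.k_neighbors)
    graph = assign_smn_graph(
        ens.A_hat, k=cfg.k_neighbors, cell_ids=kept_ids, annotations=sc.annotations
    )

    layout = None
    if compute_layout:
        logger.info("computing 3D layout (seed=%d)", cfg.seed)
        layout = layout_3d(graph, seed=cfg.seed)

    return ReconstructionResult(
        embedding=emb,
        sic_basis=basis,
        ensemble=ens,
        graph=graph,
        layout=layout,
        kept_cell_ids=kept_ids,
        config=cfg,
    )
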