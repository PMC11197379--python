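"""Reconstruct the single-cell spatial neighborhood graph.

Runs the whole transcriptome-to-space pipeline: joint CCA embedding of
reference pixels and query cells, spatial-information components (PCA of
the inter-pixel distance matrix), a seeded ensemble of neural-network
regressions from embedding to SIC scores, median cell-cell affinity with
learning-variance filtering, Gale-Shapley stable-matching neighbor
assignment, and the 3D force-directed layout.
"""

from smnchart import aggregate_to_pixels, make_query, reconstruct, simulate_layered_tissue
from smnchart.config import reduced_profile

tissue = simulate_layered_tissue(seed=1)
st = aggregate_to_pixels(tissue, pixel_size=0.2)
sc, _ = make_query(tissue, seed=1)

# reduced_profile: 3-run ensemble, <=100 epochs -- the desk-scale setting;
# PipelineConfig() gives the full published defaults (30 runs, 500 epochs).
result = reconstruct(st, sc, reduced_profile(seed=1))

print(f"kept {len(result.kept_cell_ids)} of {sc.expr.n_obs} cells "
      f"after the learning-variance filter")
print(f"SMN graph: {len(result.graph.edges)} undirected stable-matching edges "
      f"(k = {result.config.k_neighbors} rounds)")
print(f"3D layout: {result.layout.coords.shape[0]} cells embedded, "
      f"seed {result.layout.seed}")
hist = result.ensemble.histories[0]
print(f"run 1 training: {hist.stopped_epoch} epochs, "
      f"final val MSE {hist.val_loss[-1]:.4f}")
# Each cell's position is defined by its matched neighbors, not by a single
# transferred 2D coordinate; the graph is the reconstruction product.
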