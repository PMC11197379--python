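# Methods

## Model overview and assumptions

`smnchart` reconstructs single-cell spatial neighborhoods from two inputs:
an ST reference (gene × pixel counts plus per-pixel 2D coordinates) and an
SC query (gene × cell counts, optionally annotated). The method rests on
three assumptions:

1. **Spatial identity is relational.** A pixel's position is described by
   its distance profile to every other pixel, not by its raw coordinate.
   PCA of the pairwise distance matrix (rows as feature vectors, columns
   centered, no variance scaling) yields spatial-information components
   (SICs) that are invariant to rigid motions of the slide and capture
   tissue axes rather than scanner axes.
2. **Expression predicts relative position.** A regression from a joint
   expression embedding onto SIC scores, trained on reference pixels,
   transfers to query cells because both live in the same embedding space.
   This holds only to the extent that expression varies along the tissue's
   spatial axes; directions of space with no transcriptional correlate are
   unlearnable in principle.
3. **Good neighborhoods beat good coordinates.** Rather than placing each
   cell at a predicted point, cells are matched to mutually preferred
   neighbors with Gale–Shapley deferred acceptance, which prevents many
   similar cells from collapsing onto one location: a stable matching
   guarantees no cell pair would abandon their assigned partners for each
   other.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 32 | joint expression embedding dimensions |
| `d` | 32 | SIC dimensions (regression targets) |
| `n_hvg` | 2000 | shared highly variable genes for integration |
| `n_runs` | 30 | ensemble size (3 in the desk-scale profile) |
| `k_neighbors` | 30 | stable-matching rounds = max neighbors per role |
| `seed` | 60611 | base seed for every stochastic step |

**Integration** (`joint_embed`): library-size normalize each dataset to
1e4 and log1p; select HVGs by Seurat-flavor normalized dispersion computed
on the reference (the reference defines the spatial signal), intersected
with query genes; z-scale per gene within each dataset; SVD of the
gene-space cross-product of the two scaled matrices (diagonal CCA); keep
the top `q` singular-vector pairs with a deterministic sign convention and
L2-normalize each observation's row. `pca_concat` (PCA of the concatenated
rows) is available as an ablation. The embedding is invariant to
observation order and to rescaling any single observation's library.

**SIC targets**: the network's output head is ReLU-activated, so targets
must be nonnegative. The pipeline shifts each SIC dimension by its minimum
(`shift_nonnegative`) rather than min-max rescaling to [0, 1]: a pure
shift preserves the variance ordering of the components, so both the MSE
objective and the score-space distances that define affinity are dominated
by the high-variance, spatially informative SICs instead of weighting all
`d` dimensions equally. Measured on the layered-tissue fixture, switching
from a [0, 1] rescale to the shift raised training R² from ~0.03 to ~0.8
and the Spearman correlation between predicted and true cell–cell
distances from ~0.0 to ~0.4. Pairwise distances are shift-invariant, so
affinities equal those computed in the raw SIC space. A [0, 1] min-max
scaler (`scale_unit_interval`) is retained for export and inspection.

**T2S network** (`train_t2s`): fixed funnel 32–32–8–32–32 of fully
connected hidden layers — the 8-wide bottleneck forces a compressed
spatial code — each followed by batch normalization, LeakyReLU (slope
0.2) and dropout 0.2, then a ReLU output of width `d`. Adam (lr 1e-3),
MSE loss, L2 weight penalty 5e-5 (applied to weights only), minibatches of
32, at most 500 epochs, early stopping with patience 20 on a held-out 10%
validation split with best-weight restore. The implementation is pure
numpy; all randomness (Glorot initialization, split, shuffling, dropout)
flows from one seeded generator per run, so identical seeds give bitwise
identical predictions. Batch-norm uses momentum 0.99 and epsilon 1e-3;
inference disables dropout and uses running statistics.

**Ensemble affinity** (`run_ensemble`): run `r` uses seed
`base_seed + r`. Per run, affinity = 1 − per-cell min-max normalized
Euclidean distance over off-diagonal entries, then symmetrized as
(A + Aᵀ)/2 with a −inf diagonal sentinel (self-matching forbidden). The
ensemble affinity is the entrywise median (mean of the central pair for
even run counts); the learning variance matrix `M` is the entrywise sample
(n−1) variance. Cells whose row sum of `M` exceeds Q3 + 1.5·IQR
(quartiles by linear interpolation) are removed; the filter is a no-op
below two runs.

**SMN assignment** (`assign_smn_graph`): `k` sequential rounds of
host-proposing deferred acceptance. Hosts propose down their affinity row;
guests hold the best offer by their affinity column; ties break toward the
lower cell index, making the algorithm fully deterministic. After each
round the matched pairs' affinities are set to −inf in both orientations —
removal is the strongest form of down-weighting and guarantees no
duplicate edges while prioritizing still-unmatched cells. Cells may end
with fewer than `k` distinct neighbors when the pool is exhausted. Each
round makes at most c² proposals, so assignment is O(k·c²).

**Layout** (`layout_3d`): seeded 3D Fruchterman–Reingold via networkx.
Disconnected graphs are laid out per component and translated apart along
x with a warning; a single node sits at the origin.

**Neighborhood analysis**: SMN distances are unweighted shortest paths
(BFS, batched through `scipy.sparse.csgraph`). `D(x, A)` averages the `k`
nearest reachable group members; unreachable members are excluded rather
than imputed, and a cell reaching no member gets +inf — this avoids silent
bias from disconnected fragments. Spatial neighborhoods: accumulated
first-degree SMN counts (the query cell itself excluded — a pure
microenvironment signal) are normalized by median library size, log1p,
per-gene z-scaled, reduced to 32 PCs, and clustered with seeded K-means
(10 restarts) for each candidate K in 2..8; the silhouette coefficient
chooses K, ties toward smaller K (parsimony). Markers and neighbor-type
enrichment use two-sided rank-sum tests with Benjamini–Hochberg adjustment
within each comparison family. This normalization is a deliberate,
documented replacement for regularized-negative-binomial normalization,
which is out of scope.

**Benchmark metrics**: spatial distribution `P_ij = D_ij / Σ_j D_ij`;
per-cell KL uses the natural log, zero numerator terms contribute zero,
and denominators are floored at 1e-12. When graph distances feed the
metric, unreachable pairs are capped at (max finite distance + 1). The
predicted-neighbor ranking source is pluggable — SMN graph distance with
affinity tie-breaks (default) or 3D layout Euclidean distance, which
mirrors the protocol of benchmarking on visualization coordinates.

## The synthetic generator

`simulate_layered_tissue` emulates an ordered layered tissue: `L` layers
stacked along y (layer ℓ occupies y ∈ [(ℓ−1)h, ℓh)), cells uniform within
their band, each layer owning a disjoint block of marker genes expressed
at `fold`× baseline (defaults: 3 layers × 300 cells, 150 genes, 20
markers/layer, fold 5), with negative-binomial counts (variance
μ + μ²/θ, θ = 0.5). `aggregate_to_pixels` sums cells into half-open
square pixels (default size 0.2 → ~224 pixels of ~4 cells on the default
tissue), mimicking multi-cell capture; `make_query` strips coordinates and
keeps layer labels as annotations, returning truth coordinates only for
benchmarking.

What it does *not* emulate: within-layer expression gradients (the x axis
carries no transcriptional signal, so position along a layer is
unlearnable by construction), dropout structure and depth variation of
real scRNA-seq, cell-density variation, irregular tissue geometry, and
batch effects beyond a global library-size shift. Passing tests therefore
demonstrate correct mechanics and recoverable layer-scale organization,
not performance on real tissue.

## Problem sizes and profiles

The full profile reproduces the published defaults (30 runs, 500 epochs).
Tests and the acceptance script use the desk-scale profile (3 runs, ≤100
epochs, patience 10) on the default three-layer tissue — the package's
standard study condition, small enough to run on one CPU in seconds per
reconstruction while preserving every pipeline stage.

## Numerical conventions

- PCA/SVD sign convention: the largest-|loading| entry of each component
  is positive (reproducible across linear-algebra backends).
- Even-count medians are the mean of the two central values; variances use
  ddof = 1; quartiles use linear interpolation.
- A cell equidistant to all others gets zero affinities with a warning;
  a constant SIC dimension is an error for the [0,1] scaler.
- All tie-breaks (matching, ranking, gradient ordering) resolve toward the
  lower cell index via stable sorts.

## Known limitations

- The fixed neighbor count cannot adapt to cell-density variation; dense
  regions are reconstructed better than sparse ones.
- Graph distances saturate quickly on small datasets (a k=30 graph over
  ~900 cells has diameter ~5), compressing long-range order into few hops.
- The CCA integration assumes shared programs between reference and query;
  strongly batch-confounded inputs need external integration first, and
  the `method` plug point accepts alternatives.
- KL against ground truth depends on capping unreachable pairs; heavily
  fragmented graphs make the metric less interpretable.
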