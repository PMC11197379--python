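"""Synthetic layered tissues with known ground truth.

The generator emulates the study design used to validate spatial charting:
a tissue of L ordered layers stacked along the y-axis (mirroring, e.g.,
cortical layers or the suprabasal/basal/dermal axis of skin), each layer
expressing a block of marker genes at ``fold`` times the baseline, with
negative-binomial count noise (variance mu + mu^2/theta). Cells are
aggregated into square multi-cell pixels to mimic a sequencing-based ST
reference (tens-of-micron spots capturing up to ~20 cells), and the
coordinate-free single-cell query retains the layer labels as annotations
while the true coordinates are held out for benchmarking only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, QueryCells, SpatialTranscriptome


@dataclass
class SyntheticTissue:
    """Ground-truth tissue: coordinates, layer labels, counts, programs."""

    cell_coords: np.ndarray  # n x 2
    layer_labels: np.ndarray  # n, values 1..L
    counts: np.ndarray  # genes x n, nonnegative integers
    program_means: np.ndarray  # L x genes expected expression
    gene_ids: list[str]
    cell_ids: list[str]
    seed: int

    @property
    def n_cells(self) -> int:
        return self.cell_coords.shape[0]

    @property
    def n_layers(self) -> int:
        return self.program_means.shape[0]


def simulate_layered_tissue(
    L: int = 3,
    cells_per_layer: int = 300,
    n_genes: int = 150,
    markers_per_layer: int = 20,
    fold: float = 5.0,
    dispersion: float = 0.5,
    base_mean: float = 1.0,
    layer_height: float = 1.0,
    seed: int = 0,
) -> SyntheticTissue:
    """Simulate an L-layer tissue with layer-specific marker programs.

    Layer l occupies the horizontal band y in [(l-1)h, lh); x spans
    [0, L*h) so the tissue is square. Gene g has mean ``base_mean``
    everywhere, elevated to ``fold * base_mean`` for the marker block of its
    layer; counts are negative binomial with variance mu + mu^2/theta.
    Fully reproducible from the seed.
    """
    if L < 2:
        raise ValueError("need at least 2 layers")
    if markers_per_layer * L > n_genes:
        raise ValueError("marker blocks exceed the gene count")
    if cells_per_layer < 1 or fold <= 0 or dispersion <= 0 or base_mean <= 0:
        raise ValueError("invalid parameter ranges")
    rng = np.random.default_rng(seed)

    n = L * cells_per_layer
    width = L * layer_height
    coords = np.empty((n, 2))
    labels = np.empty(n, dtype=int)
    for l in range(L):
        sl = slice(l * cells_per_layer, (l + 1) * cells_per_layer)
        coords[sl, 0] = rng.uniform(0, width, cells_per_layer)
        coords[sl, 1] = rng.uniform(l * layer_height, (l + 1) * layer_height, cells_per_layer)
        labels[sl] = l + 1

    program_means = np.full((L, n_genes), base_mean)
    for l in range(L):
        block = slice(l * markers_per_layer, (l + 1) * markers_per_layer)
        program_means[l, block] = fold * base_mean

    mu = program_means[labels - 1].T  # genes x cells
    theta = dispersion
    # NB(mean mu, dispersion theta): p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)

    return SyntheticTissue(
        cell_coords=coords,
        layer_labels=labels,
        counts=counts,
        program_means=program_means,
        gene_ids=[f"gene{g}" for g in range(n_genes)],
        cell_ids=[f"cell{i}" for i in range(n)],
        seed=seed,
    )


def aggregate_to_pixels(tissue: SyntheticTissue, pixel_size: float = 0.2) -> SpatialTranscriptome:
    """Aggregate cells into square multi-cell pixels (a Visium-like reference).

    A pixel covers the half-open square [x, x+s) x [y, y+s); its expression
    is the summed counts of the cells it captures and its coordinate is the
    pixel center. Empty pixels are dropped; total counts are conserved.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ix = np.floor(tissue.cell_coords[:, 0] / pixel_size).astype(int)
    iy = np.floor(tissue.cell_coords[:, 1] / pixel_size).astype(int)
    keys = np.stack([ix, iy], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    if uniq.shape[0] == 0:
        raise ValueError("all pixels empty")
    n_pix = uniq.shape[0]
    pix_counts = np.zeros((tissue.counts.shape[0], n_pix))
    np.add.at(pix_counts.T, inverse, tissue.counts.T)
    centers = (uniq + 0.5) * pixel_size
    expr = ExpressionMatrix(
        counts=pix_counts,
        gene_ids=list(tissue.gene_ids),
        obs_ids=[f"pixel{i}" for i in range(n_pix)],
    )
    return SpatialTranscriptome(expr=expr, coords=centers)


def make_query(
    tissue: SyntheticTissue, subsample_fraction: float = 1.0, seed: int = 0
) -> tuple[QueryCells, np.ndarray]:
    """Strip coordinates to form the SC query; truth coords are held out.

    Returns (QueryCells with layer annotations, ground-truth coordinates of
    the selected cells). Subsampling is uniform without replacement.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    n = tissue.n_cells
    n_take = int(round(subsample_fraction * n))
    if n_take < 10:
        raise ValueError("subsample would keep fewer than 10 cells")
    if n_take == n:
        idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=n_take, replace=False))
    expr = ExpressionMatrix(
        counts=tissue.counts[:, idx],
        gene_ids=list(tissue.gene_ids),
        obs_ids=[tissue.cell_ids[i] for i in idx],
    )
    annotations = {
        tissue.cell_ids[i]: f"layer{tissue.layer_labels[i]}" for i in idx
    }
    return QueryCells(expr=expr, annotations=annotations), tissue.cell_coords[idx]
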