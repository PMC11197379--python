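"""Spatial-information components (SICs).

A pixel's spatial identity is described not by its 2D coordinate but by its
distance profile to every other pixel of the reference. SICs are the
principal components of this pairwise Euclidean distance matrix: each
pixel's row of distances is the feature vector, columns are centered, and
the top ``d`` components (default 32) become the regression targets of the
transcriptome-to-space model. Because a ReLU output head cannot emit
negative values, the signed PCA scores are shifted to be nonnegative
before training (`shift_nonnegative`); a min-max [0, 1] rescale is also
provided (`scale_unit_interval`) for inspection and export, but the
pipeline trains on the shift-only transform because it preserves the
variance ordering of the components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with zero diagonal."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("D must be symmetric within 1e-9")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("D must have zero diagonal")
        if np.any(self.D < 0):
            raise ValueError("D must be nonnegative")

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class SICBasis:
    """PCA of the distance matrix: scores are the training targets."""

    scores: np.ndarray  # pixels x d
    loadings: np.ndarray  # pixels x d (unit-norm principal axes)
    explained_variance: np.ndarray  # length d, nonincreasing
    scaler: np.ndarray | None = None  # d x 2 array of (min, max), set by scaling

    @property
    def d(self) -> int:
        return self.scores.shape[1]


def pairwise_pixel_distance(coords: np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix between pixel coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 pixels with coordinate rows")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return DistanceMatrix(D=squareform(pdist(coords, metric="euclidean")))


def compute_sics(D: DistanceMatrix, d: int = 32) -> SICBasis:
    """PCA on the rows of the distance matrix.

    Columns are centered (no variance scaling). Returns min(d, p-1, rank)
    components with a warning when truncated. Sign convention: each
    component's largest-|loading| entry is positive, so scores are
    reproducible across linear-algebra backends.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    M = D.D
    p = M.shape[0]
    centered = M - M.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("all pixels identical: distance matrix is constant")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max() * max(M.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    d_eff = min(d, p - 1, rank)
    if d_eff < d:
        logger.warning("SIC basis truncated from %d to %d components", d, d_eff)
    loadings = Vt.T[:, :d_eff]
    # deterministic sign: largest-|entry| loading positive per component
    for j in range(d_eff):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings
    explained = (s[:d_eff] ** 2) / (p - 1)
    return SICBasis(scores=scores, loadings=loadings, explained_variance=explained)


def scale_unit_interval(basis: SICBasis) -> SICBasis:
    """Min-max map each score dimension to [0, 1]; stores the scaler.

    The affine map is invertible within 1e-9; values outside the training
    range map outside [0, 1] (no clipping).
    """
    lo = basis.scores.min(axis=0)
    hi = basis.scores.max(axis=0)
    if np.any(hi - lo == 0):
        raise ValueError("cannot scale a constant score dimension")
    scaled = (basis.scores - lo) / (hi - lo)
    return replace(basis, scores=scaled, scaler=np.column_stack([lo, hi]))


def shift_nonnegative(basis: SICBasis) -> SICBasis:
    """Shift each score dimension so its minimum is zero (scale preserved).

    This is the transform the reconstruction pipeline trains on: a ReLU
    output head cannot emit negative values, so the signed PCA scores must
    be made nonnegative -- but a pure shift, unlike a min-max rescale,
    preserves the variance ordering of the components. High-variance SICs
    carry the spatial signal, and both the MSE training objective and the
    score-space distances that define cell-cell affinity should be
    dominated by them, not by the near-noise trailing components. Pairwise
    distances are invariant to the shift, so affinities computed on shifted
    predictions equal those in the original SIC space. The scaler records
    the shift as a unit-scale affine map (min, min + 1).
    """
    lo = basis.scores.min(axis=0)
    return replace(
        basis,
        scores=basis.scores - lo,
        scaler=np.column_stack([lo, lo + 1.0]),
    )


def apply_scaler(scores: np.ndarray, scaler: np.ndarray) -> np.ndarray:
    """Apply a stored (min, max) scaler to new scores (no clipping)."""
    lo, hi = scaler[:, 0], scaler[:, 1]
    return (scores - lo) / (hi - lo)


def invert_scaler(scaled: np.ndarray, scaler: np.ndarray) -> np.ndarray:
    lo, hi = scaler[:, 0], scaler[:, 1]
    return scaled * (hi - lo) + lo
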