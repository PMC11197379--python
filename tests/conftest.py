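import logging

import numpy as np
import pytest

from smnchart import (
    QueryCells,
    SpatialTranscriptome,
    aggregate_to_pixels,
    make_query,
    reconstruct,
    simulate_layered_tissue,
)
from smnchart.config import PipelineConfig, T2SConfig

logging.getLogger("smnchart").setLevel(logging.ERROR)


def tiny_profile(seed: int = 0, k: int = 10, n_runs: int = 2) -> PipelineConfig:
    """Small-but-real pipeline settings for fast unit tests."""
    return PipelineConfig(
        n_runs=n_runs,
        k_neighbors=k,
        seed=seed,
        t2s=T2SConfig(epochs=30, patience=5),
    )


@pytest.fixture(scope="session")
def small_tissue():
    return simulate_layered_tissue(
        L=3, cells_per_layer=80, n_genes=90, markers_per_layer=15, seed=7
    )


@pytest.fixture(scope="session")
def small_inputs(small_tissue):
    st = aggregate_to_pixels(small_tissue, pixel_size=0.35)
    sc, truth = make_query(small_tissue, seed=7)
    return st, sc, truth


@pytest.fixture(scope="session")
def small_reconstruction(small_inputs):
    st, sc, truth = small_inputs
    return reconstruct(st, sc, tiny_profile(seed=7), compute_layout=True)
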