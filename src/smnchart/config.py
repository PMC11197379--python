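"""Pipeline configuration.

Defaults mirror the method's published settings: 32 embedding dimensions,
32 spatial-information components, a 30-run ensemble, 30 stable-matching
neighbors per cell and the fixed random seed 60611.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class T2SConfig:
    """Hyperparameters of the transcriptome-to-space network.

    The architecture is a fixed funnel 32-32-8-32-32 of fully connected
    hidden layers (the 8-wide bottleneck compresses the spatial code), each
    followed by batch normalization, LeakyReLU (slope 0.2) and dropout 0.2,
    with a ReLU output head of width d. Training uses Adam (lr 1e-3), MSE
    loss, an L2 weight penalty alpha = 5e-5, minibatches of 32, at most 500
    epochs, and early stopping with patience 20 on a held-out 10% validation
    split, restoring the best-validation weights.
    """

    layer_widths: tuple[int, ...] = (32, 32, 8, 32, 32)
    dropout: float = 0.2
    batch_norm: bool = True
    leaky_slope: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 500
    patience: int = 20
    batch_size: int = 32
    alpha: float = 0.00005  # L2 weight penalty
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class PipelineConfig:
    """End-to-end reconstruction settings."""

    q: int = 32  # joint embedding dimensions
    d: int = 32  # spatial-information components
    n_runs: int = 30  # ensemble size
    k_neighbors: int = 30  # stable-matching neighbors per cell
    seed: int = 60611
    n_hvg: int = 2000
    t2s: T2SConfig = field(default_factory=T2SConfig)

    def __post_init__(self) -> None:
        for name in ("q", "d", "n_runs", "k_neighbors", "n_hvg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


#: Desk-scale profile for quick runs and continuous testing; the full
#: profile (the dataclass defaults) matches the published settings.
def reduced_profile(seed: int = 60611) -> PipelineConfig:
    return PipelineConfig(
        n_runs=3,
        seed=seed,
        t2s=T2SConfig(epochs=100, patience=10),
    )
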