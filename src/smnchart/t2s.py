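"""The transcriptome-to-space (T2S) projection.

A fixed multilayer perceptron maps the q-dimensional joint expression
embedding of a reference pixel onto its scaled spatial-information scores:
hidden widths 32-32-8-32-32 (the 8-wide bottleneck forces a compressed
spatial code), each hidden layer followed by batch normalization, LeakyReLU
(slope 0.2) and dropout 0.2, then a ReLU-activated output of width d.
Training minimizes MSE with Adam (lr 1e-3), an L2 weight penalty
alpha = 5e-5, minibatches of 32, at most 500 epochs, and early stopping
(patience 20) on a held-out 10% validation split with best-weight restore.

Because any single network's prediction is noisy, the model is trained as an
ensemble of n (default 30) independently seeded runs. Each run's predicted
cell scores yield a cell-cell affinity matrix (1 minus the per-cell min-max
normalized Euclidean distance in score space, symmetrized); the ensemble
affinity is the entrywise median, and the entrywise variance across runs --
the learning variance matrix M -- flags cells whose placement the model
cannot learn stably. Cells whose total variance exceeds Q3 + 1.5 IQR are
filtered out before neighbor assignment.

All randomness (initialization, validation split, shuffling, dropout) flows
from a single seeded generator per run, so identical seeds give bitwise
identical predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import T2SConfig

logger = logging.getLogger(__name__)

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-7


@dataclass
class LossHistory:
    train_loss: list[float]
    val_loss: list[float]
    stopped_epoch: int
    early_stopped: bool


@dataclass
class T2SModel:
    params: dict[str, np.ndarray]
    config: T2SConfig
    history: LossHistory
    run_seed: int
    n_in: int
    n_out: int


@dataclass
class EnsembleAffinity:
    """Per-run and median affinities plus the learning variance matrix."""

    A_runs: list[np.ndarray]
    A_hat: np.ndarray
    M: np.ndarray
    kept_cells: np.ndarray  # indices into the original cell order
    histories: list[LossHistory] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.A_runs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(rng: np.random.Generator, widths: list[int], batch_norm: bool) -> dict:
    params: dict[str, np.ndarray] = {}
    n_hidden = len(widths) - 2
    for i in range(len(widths) - 1):
        params[f"W{i}"] = _glorot(rng, widths[i], widths[i + 1])
        params[f"b{i}"] = np.zeros(widths[i + 1])
        if batch_norm and i < n_hidden:
            params[f"gamma{i}"] = np.ones(widths[i + 1])
            params[f"beta{i}"] = np.zeros(widths[i + 1])
            params[f"rmean{i}"] = np.zeros(widths[i + 1])
            params[f"rvar{i}"] = np.ones(widths[i + 1])
    return params


def _forward(
    params: dict,
    X: np.ndarray,
    cfg: T2SConfig,
    n_hidden: int,
    training: bool,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (output, cache) where cache feeds backward."""
    cache: list[dict] = []
    h = X
    for i in range(n_hidden):
        z = h @ params[f"W{i}"] + params[f"b{i}"]
        layer: dict = {"x": h, "z": z}
        if cfg.batch_norm:
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                params[f"rmean{i}"] = (
                    _BN_MOMENTUM * params[f"rmean{i}"] + (1 - _BN_MOMENTUM) * mu
                )
                params[f"rvar{i}"] = (
                    _BN_MOMENTUM * params[f"rvar{i}"] + (1 - _BN_MOMENTUM) * var
                )
            else:
                mu = params[f"rmean{i}"]
                var = params[f"rvar{i}"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv_std
            z = params[f"gamma{i}"] * xhat + params[f"beta{i}"]
            layer.update(xhat=xhat, inv_std=inv_std)
        a = np.where(z > 0, z, cfg.leaky_slope * z)
        layer["pre_act"] = z
        if training and cfg.dropout > 0:
            mask = (rng.random(a.shape) >= cfg.dropout) / (1 - cfg.dropout)
            a = a * mask
            layer["drop_mask"] = mask
        cache.append(layer)
        h = a
    i = n_hidden
    z_out = h @ params[f"W{i}"] + params[f"b{i}"]
    out = np.maximum(z_out, 0.0)
    cache.append({"x": h, "pre_act": z_out})
    return out, cache


def _backward(
    params: dict, cache: list[dict], d_out: np.ndarray, cfg: T2SConfig, n_hidden: int
) -> dict:
    grads: dict[str, np.ndarray] = {}
    i = n_hidden
    layer = cache[i]
    dz = d_out * (layer["pre_act"] > 0)  # ReLU head
    grads[f"W{i}"] = layer["x"].T @ dz + cfg.alpha * params[f"W{i}"]
    grads[f"b{i}"] = dz.sum(axis=0)
    dh = dz @ params[f"W{i}"].T
    for i in range(n_hidden - 1, -1, -1):
        layer = cache[i]
        if "drop_mask" in layer:
            dh = dh * layer["drop_mask"]
        da = np.where(layer["pre_act"] > 0, dh, cfg.leaky_slope * dh)
        if cfg.batch_norm:
            xhat, inv_std = layer["xhat"], layer["inv_std"]
            grads[f"gamma{i}"] = (da * xhat).sum(axis=0)
            grads[f"beta{i}"] = da.sum(axis=0)
            n = da.shape[0]
            dxhat = da * params[f"gamma{i}"]
            dz = inv_std * (
                dxhat
                - dxhat.mean(axis=0)
                - xhat * (dxhat * xhat).mean(axis=0)
            )
        else:
            dz = da
        grads[f"W{i}"] = layer["x"].T @ dz + cfg.alpha * params[f"W{i}"]
        grads[f"b{i}"] = dz.sum(axis=0)
        dh = dz @ params[f"W{i}"].T
    return grads


def train_t2s(
    X_st: np.ndarray,
    targets: np.ndarray,
    config: T2SConfig | None = None,
    seed: int = 60611,
) -> T2SModel:
    """Train the T2S network on (pixel embedding -> scaled SIC scores).

    Deterministic given the seed; stops at the first epoch where validation
    loss has not improved for ``patience`` epochs and restores the
    best-validation weights.
    """
    cfg = config or T2SConfig()
    X_st = np.asarray(X_st, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.isnan(X_st).any() or np.isnan(targets).any():
        raise ValueError("NaNs in training input")
    p, q = X_st.shape
    d = targets.shape[1]
    if targets.shape[0] != p:
        raise ValueError("X_st and targets row counts differ")
    if p < 2 * cfg.batch_size:
        logger.warning(
            "only %d training pixels for batch size %d", p, cfg.batch_size
        )

    rng = np.random.default_rng(seed)
    widths = [q, *cfg.layer_widths, d]
    n_hidden = len(cfg.layer_widths)
    params = _init_params(rng, widths, cfg.batch_norm)

    # held-out validation split for early stopping
    n_val = max(1, int(round(cfg.val_fraction * p)))
    perm = rng.permutation(p)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, y_tr = X_st[tr_idx], targets[tr_idx]
    X_val, y_val = X_st[val_idx], targets[val_idx]

    m = {k: np.zeros_like(v) for k, v in params.items() if k[0] in "Wbgb"}
    v = {k: np.zeros_like(val) for k, val in m.items()}
    trainable = [k for k in params if k.startswith(("W", "b", "gamma", "beta"))]
    t = 0

    best_val = np.inf
    best_params: dict | None = None
    wait = 0
    train_hist: list[float] = []
    val_hist: list[float] = []
    early = False
    stopped = cfg.epochs

    n_tr = len(tr_idx)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            out, cache = _forward(params, xb, cfg, n_hidden, True, rng)
            resid = out - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            epoch_loss += loss * len(idx)
            d_out = 2.0 * resid / resid.size
            grads = _backward(params, cache, d_out, cfg, n_hidden)
            t += 1
            for k in trainable:
                g = grads[k]
                m[k] = _ADAM_B1 * m[k] + (1 - _ADAM_B1) * g
                v[k] = _ADAM_B2 * v[k] + (1 - _ADAM_B2) * g**2
                mhat = m[k] / (1 - _ADAM_B1**t)
                vhat = v[k] / (1 - _ADAM_B2**t)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        train_hist.append(epoch_loss / n_tr)

        val_out, _ = _forward(params, X_val, cfg, n_hidden, False)
        val_loss = float(np.mean((val_out - y_val) ** 2))
        val_hist.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p_.copy() for k, p_ in params.items()}
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                early = True
                stopped = epoch + 1
                break

    if best_params is not None:
        params = best_params
    history = LossHistory(
        train_loss=train_hist,
        val_loss=val_hist,
        stopped_epoch=min(stopped, len(train_hist)),
        early_stopped=early,
    )
    return T2SModel(
        params=params, config=cfg, history=history, run_seed=seed, n_in=q, n_out=d
    )


def predict_sic_scores(model: T2SModel, Y_sc: np.ndarray) -> np.ndarray:
    """Predict scaled SIC scores for query cells (inference mode).

    Dropout is off and batch normalization uses the running statistics, so
    duplicated input rows produce identical output rows. Output is
    entrywise nonnegative (ReLU head).
    """
    Y_sc = np.asarray(Y_sc, dtype=float)
    if Y_sc.ndim != 2 or Y_sc.shape[1] != model.n_in:
        raise ValueError(
            f"input width {Y_sc.shape[-1]} != model input width {model.n_in}"
        )
    out, _ = _forward(
        model.params, Y_sc, model.config, len(model.config.layer_widths), False
    )
    return out


def affinity_from_scores(P: np.ndarray) -> np.ndarray:
    """Cell-cell affinity from predicted SIC scores.

    Euclidean distance in score space, per-cell min-max normalized over the
    off-diagonal entries, affinity = 1 - normalized distance, symmetrized as
    (A + A^T)/2 with a -inf diagonal sentinel (self-matching forbidden).
    """
    P = np.asarray(P, dtype=float)
    c = P.shape[0]
    if c < 2:
        raise ValueError("need at least 2 cells")
    dist = cdist(P, P)
    off = ~np.eye(c, dtype=bool)
    A = np.zeros((c, c))
    for i in range(c):
        row = dist[i][off[i]]
        lo, hi = row.min(), row.max()
        if hi == lo:
            logger.warning("cell %d equidistant to all others; affinities set to 0", i)
            continue
        A[i][off[i]] = 1.0 - (row - lo) / (hi - lo)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, -np.inf)
    return A


def run_ensemble(
    X_st: np.ndarray,
    targets: np.ndarray,
    Y_sc: np.ndarray,
    config: T2SConfig | None = None,
    n_runs: int = 30,
    base_seed: int = 60611,
) -> EnsembleAffinity:
    """Train n seeded runs (seed = base_seed + r) and aggregate affinities.

    The ensemble affinity is the entrywise median of the per-run matrices;
    the learning variance matrix M is the entrywise sample variance (zero
    for a single run). Loss histories of every run are retained.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = config or T2SConfig()
    A_runs: list[np.ndarray] = []
    histories: list[LossHistory] = []
    for r in range(n_runs):
        model = train_t2s(X_st, targets, cfg, seed=base_seed + r)
        P = predict_sic_scores(model, Y_sc)
        A_runs.append(affinity_from_scores(P))
        histories.append(model.history)
    stack = np.stack(A_runs)
    A_hat = np.median(stack, axis=0)
    c = A_hat.shape[0]
    if n_runs == 1:
        M = np.zeros((c, c))
    else:
        with np.errstate(invalid="ignore"):
            M = np.var(stack, axis=0, ddof=1)
        np.fill_diagonal(M, 0.0)  # -inf sentinel diagonal carries no variance
    np.fill_diagonal(A_hat, -np.inf)
    return EnsembleAffinity(
        A_runs=A_runs,
        A_hat=A_hat,
        M=M,
        kept_cells=np.arange(c),
        histories=histories,
    )


def filter_high_variance_cells(ens: EnsembleAffinity) -> EnsembleAffinity:
    """Drop cells whose total learning variance exceeds Q3 + 1.5 IQR.

    Per-cell total variance is the row sum of M; quartiles use linear
    interpolation. With a single run this is a no-op (warning). Raises if
    every cell would be removed.
    """
    if ens.n_runs < 2:
        logger.warning("variance filter skipped: fewer than 2 ensemble runs")
        return ens
    total = ens.M.sum(axis=1)
    q1, q3 = np.percentile(total, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    keep = total <= threshold
    if not keep.any():
        raise ValueError("variance filter removed every cell: degenerate ensemble")
    if keep.all():
        return ens
    idx = np.flatnonzero(keep)
    return EnsembleAffinity(
        A_runs=[A[np.ix_(idx, idx)] for A in ens.A_runs],
        A_hat=ens.A_hat[np.ix_(idx, idx)],
        M=ens.M[np.ix_(idx, idx)],
        kept_cells=ens.kept_cells[idx],
        histories=ens.histories,
    )
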