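import numpy as np
import pytest

from smnchart import (
    EnsembleAffinity,
    affinity_from_scores,
    filter_high_variance_cells,
    predict_sic_scores,
    run_ensemble,
    train_t2s,
)
from smnchart.config import T2SConfig


@pytest.fixture(scope="module")
def linear_task():
    """Targets are a fixed linear map of the inputs plus small noise."""
    rng = np.random.default_rng(42)
    p, q, d = 200, 8, 4
    X = rng.normal(size=(p, q))
    W = rng.normal(size=(q, d))
    noise = 0.05
    Y = X @ W + rng.normal(scale=noise, size=(p, d))
    Y = Y - Y.min(axis=0)  # nonnegative, as the pipeline trains
    return X, Y, noise


@pytest.fixture(scope="module")
def quick_cfg():
    return T2SConfig(epochs=150, patience=30)


class TestTraining:
    def test_loss_decreases_on_learnable_task(self, linear_task, quick_cfg):
        X, Y, _ = linear_task
        model = train_t2s(X, Y, quick_cfg, seed=1)
        hist = model.history.train_loss
        assert hist[-1] < 0.10 * hist[0]

    def test_identical_seed_identical_predictions(self, linear_task, quick_cfg):
        X, Y, _ = linear_task
        m1 = train_t2s(X, Y, quick_cfg, seed=9)
        m2 = train_t2s(X, Y, quick_cfg, seed=9)
        np.testing.assert_array_equal(
            predict_sic_scores(m1, X), predict_sic_scores(m2, X)
        )

    def test_early_stop_on_noise_targets(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 6))
        Y = np.abs(rng.normal(size=(120, 3)))  # pure noise, nothing to learn
        cfg = T2SConfig(epochs=500, patience=20)
        model = train_t2s(X, Y, cfg, seed=2)
        assert model.history.early_stopped
        assert model.history.stopped_epoch <= 500
        assert len(model.history.train_loss) == len(model.history.val_loss)

    def test_nan_input_rejected(self, quick_cfg):
        X = np.zeros((40, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_t2s(X, np.zeros((40, 2)), quick_cfg, seed=0)


class TestPrediction:
    def test_recovery_on_training_pixels(self, linear_task, quick_cfg):
        X, Y, noise = linear_task
        model = train_t2s(X, Y, quick_cfg, seed=4)
        pred = predict_sic_scores(model, X)
        rmse = np.sqrt(np.mean((pred - Y) ** 2))
        # the fixed architecture is heavily regularized (dropout, weight
        # penalty), so demand substantial -- not noise-floor -- recovery
        assert rmse < 0.5 * Y.std()

    def test_output_nonnegative(self, linear_task, quick_cfg):
        X, Y, _ = linear_task
        model = train_t2s(X, Y, quick_cfg, seed=5)
        rng = np.random.default_rng(0)
        pred = predict_sic_scores(model, rng.normal(size=(50, X.shape[1])))
        assert pred.min() >= 0

    def test_duplicated_rows_identical_outputs(self, linear_task, quick_cfg):
        X, Y, _ = linear_task
        model = train_t2s(X, Y, quick_cfg, seed=6)
        doubled = np.vstack([X[:5], X[:5]])
        pred = predict_sic_scores(model, doubled)
        np.testing.assert_array_equal(pred[:5], pred[5:])

    def test_width_mismatch_rejected(self, linear_task, quick_cfg):
        X, Y, _ = linear_task
        model = train_t2s(X, Y, quick_cfg, seed=7)
        with pytest.raises(ValueError):
            predict_sic_scores(model, np.zeros((3, X.shape[1] + 1)))


class TestAffinity:
    def test_monotone_in_distance(self):
        P = np.array([[0.0], [1.0], [10.0]])
        A = affinity_from_scores(P)
        assert A[0, 1] > A[0, 2]

    def test_symmetric_with_minus_inf_diagonal(self):
        P = np.random.default_rng(1).normal(size=(6, 3))
        A = affinity_from_scores(P)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(A[off], A.T[off])
        assert np.all(np.isneginf(np.diag(A)))

    def test_matches_brute_force_oracle(self):
        """Entrywise agreement with a double-loop reference implementation."""
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 4))
        c = 8
        dist = np.zeros((c, c))
        for i in range(c):
            for j in range(c):
                dist[i, j] = np.sqrt(((P[i] - P[j]) ** 2).sum())
        expected = np.zeros((c, c))
        for i in range(c):
            row = np.delete(dist[i], i)
            lo, hi = row.min(), row.max()
            for j in range(c):
                if j != i:
                    expected[i, j] = 1 - (dist[i, j] - lo) / (hi - lo)
        expected = (expected + expected.T) / 2
        np.fill_diagonal(expected, -np.inf)
        np.testing.assert_allclose(affinity_from_scores(P), expected, atol=1e-12)

    def test_row_normalization_spans_unit_interval(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(7, 2))
        A = affinity_from_scores(P)
        # after symmetrization the extremes persist as bounds
        off = ~np.eye(7, dtype=bool)
        assert A[off].max() <= 1.0 + 1e-12
        assert A[off].min() >= -1e-12


class TestEnsemble:
    def test_single_run_median_and_zero_variance(self, linear_task):
        X, Y, _ = linear_task
        cfg = T2SConfig(epochs=10, patience=3)
        ens = run_ensemble(X, Y, X[:20], cfg, n_runs=1, base_seed=0)
        np.testing.assert_array_equal(ens.A_hat, ens.A_runs[0])
        assert np.all(ens.M == 0)

    def test_repeated_ensemble_identical(self, linear_task):
        X, Y, _ = linear_task
        cfg = T2SConfig(epochs=10, patience=3)
        e1 = run_ensemble(X, Y, X[:15], cfg, n_runs=3, base_seed=11)
        e2 = run_ensemble(X, Y, X[:15], cfg, n_runs=3, base_seed=11)
        np.testing.assert_array_equal(e1.A_hat, e2.A_hat)
        np.testing.assert_array_equal(e1.M, e2.M)

    def test_median_permutation_invariant_in_run_order(self, linear_task):
        X, Y, _ = linear_task
        cfg = T2SConfig(epochs=10, patience=3)
        ens = run_ensemble(X, Y, X[:15], cfg, n_runs=3, base_seed=11)
        stack = np.stack(ens.A_runs[::-1])
        reordered = np.median(stack, axis=0)
        np.fill_diagonal(reordered, -np.inf)
        np.testing.assert_array_equal(reordered, ens.A_hat)


def _fake_ensemble(per_cell_variance):
    """Ensemble whose M row sums equal the requested per-cell variances."""
    c = len(per_cell_variance)
    M = np.zeros((c, c))
    for i, v in enumerate(per_cell_variance):
        M[i, (i + 1) % c] = v
    A = np.zeros((c, c))
    return EnsembleAffinity(
        A_runs=[A.copy(), A.copy()],
        A_hat=A.copy(),
        M=M,
        kept_cells=np.arange(c),
    )


class TestVarianceFilter:
    def test_outlier_cell_removed(self):
        ens = _fake_ensemble([1.0, 1.0, 1.0, 1.0, 100.0])
        kept = filter_high_variance_cells(ens).kept_cells
        np.testing.assert_array_equal(kept, [0, 1, 2, 3])

    def test_equal_variances_keep_all(self):
        ens = _fake_ensemble([2.0] * 6)
        kept = filter_high_variance_cells(ens).kept_cells
        np.testing.assert_array_equal(kept, np.arange(6))

    def test_single_run_noop(self):
        ens = _fake_ensemble([1.0, 50.0, 1.0])
        ens.A_runs = ens.A_runs[:1]
        kept = filter_high_variance_cells(ens).kept_cells
        np.testing.assert_array_equal(kept, np.arange(3))
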