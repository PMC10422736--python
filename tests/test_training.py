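"""Normalization, fold plans, metrics and the optimization loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnyield._autodiff import Tensor
from rxnyield.training import (
    Adam,
    DegenerateDataError,
    OptimizerConfig,
    OutcomeScaler,
    early_stopped_loop,
    evaluate,
    make_folds,
    mse_loss,
    summarize_metrics,
    train_val_test_split,
)


class TestScaler:
    def test_two_point_symmetry(self):
        s = OutcomeScaler.fit(np.array([0.0, 10.0]))
        assert s.mu == 5.0 and s.sigma == 5.0
        np.testing.assert_array_equal(s.transform([0.0, 10.0]), [-1.0, 1.0])

    def test_transformed_training_outcomes_standardized(self, rng):
        x = rng.normal(3.0, 2.5, size=200)
        s = OutcomeScaler.fit(x)
        z = s.transform(x)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=30
        ).filter(lambda xs: np.std(xs) > 1e-6)
    )
    def test_roundtrip(self, xs):
        s = OutcomeScaler.fit(np.array(xs))
        np.testing.assert_allclose(
            s.inverse_transform(s.transform(xs)), xs, atol=1e-9 * (1 + np.max(np.abs(xs)))
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            OutcomeScaler.fit(np.array([3.0, 3.0, 3.0]))
        with pytest.raises(DegenerateDataError):
            OutcomeScaler.fit(np.array([1.0]))


class TestFolds:
    def test_partition_n100_k10(self):
        plan = make_folds(100, 10, seed=1)
        tests = [t for _, _, t in plan.folds]
        assert all(len(t) == 10 for t in tests)
        assert sorted(np.concatenate(tests).tolist()) == list(range(100))

    def test_fold_sizes_n1558_k5(self):
        plan = make_folds(1558, 5, seed=0)
        sizes = sorted(len(t) for _, _, t in plan.folds)
        assert sizes == [311, 311, 312, 312, 312]

    def test_disjoint_and_val_share(self):
        plan = make_folds(100, 5, val_fraction=0.2, seed=3)
        for train, val, test in plan.folds:
            assert len(np.intersect1d(train, val)) == 0
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.intersect1d(val, test)) == 0
            assert len(val) == 16  # 20% of the 80-sample training portion
            assert len(train) == 64

    def test_reproducible_for_fixed_seed(self):
        p1 = make_folds(50, 5, seed=9)
        p2 = make_folds(50, 5, seed=9)
        for (a, b, c), (x, y, z) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a, x)
            np.testing.assert_array_equal(c, z)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_folds(5, 10)
        with pytest.raises(ValueError):
            make_folds(10, 1)

    def test_single_split_ratios(self):
        train, val, test = train_val_test_split(100, seed=0)
        assert len(test) == 20
        assert len(val) == 16
        assert len(train) == 64
        assert len(np.union1d(np.union1d(train, val), test)) == 100


class TestMetrics:
    def test_perfect_predictions(self):
        m = evaluate(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert (m.r2, m.mae, m.rmse) == (1.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        m = evaluate(np.array([0.0, 1, 5]), np.array([0.0, 1, 2]))
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(3.0))

    def test_scale_invariance_of_pearson_r2(self, rng):
        obs = rng.normal(size=50)
        pred = obs + rng.normal(0, 0.1, size=50)
        m1 = evaluate(pred, obs)
        m2 = evaluate(2 * pred, obs)
        assert m2.r2 == pytest.approx(m1.r2)
        assert m2.mae > m1.mae

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_rmse_at_least_mae(self, seed):
        r = np.random.default_rng(seed)
        obs = r.normal(size=20)
        pred = obs + r.normal(size=20)
        m = evaluate(pred, obs)
        assert m.rmse >= m.mae >= 0.0
        assert m.r2 <= 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), np.zeros(4))
        with pytest.raises(DegenerateDataError):
            evaluate(np.array([1.0, 2.0]), np.array([5.0, 5.0]))

    def test_summary_mean_matches_recomputation(self):
        ms = [evaluate(np.array([0.0, 1, 2]), np.array([0.0, 1, 1 + i])) for i in (1, 2)]
        s = summarize_metrics(ms)
        assert s["mae"]["mean"] == pytest.approx(np.mean([m.mae for m in ms]), abs=1e-12)
        assert s["rmse"]["std"] == pytest.approx(np.std([m.rmse for m in ms]), abs=1e-12)


class TestOptimization:
    def test_adam_minimizes_quadratic(self):
        w = Tensor(np.array([5.0, -3.0]))
        opt = Adam({"w": w}, OptimizerConfig(learning_rate=0.1))
        for _ in range(300):
            opt.zero_grad()
            loss = (w * w).sum()
            loss.backward()
            opt.step()
        assert np.abs(w.data).max() < 1e-3

    def test_mse_loss_value(self):
        loss = mse_loss(Tensor(np.array([1.0, 2.0])), np.array([0.0, 0.0]))
        assert float(loss.data) == pytest.approx(2.5)

    def test_early_stopping_patience_zero(self):
        """patience=0 stops at the first epoch without val improvement."""
        vals = iter([1.0, 0.5, 0.6, 0.4, 0.3])
        log = early_stopped_loop(
            n_train=4,
            step_fn=lambda idx: 0.0,
            val_fn=lambda: next(vals),
            snapshot_fn=lambda: None,
            restore_fn=lambda s: None,
            config=OptimizerConfig(max_epochs=10, patience=0, batch_size=2),
            rng=np.random.default_rng(0),
        )
        assert len(log) == 3  # stops right after the 0.6 epoch

    def test_divergence_aborts(self):
        with pytest.raises(FloatingPointError):
            early_stopped_loop(
                n_train=2,
                step_fn=lambda idx: float("nan"),
                val_fn=lambda: 1.0,
                snapshot_fn=lambda: None,
                restore_fn=lambda s: None,
                config=OptimizerConfig(max_epochs=3, batch_size=2),
                rng=np.random.default_rng(0),
            )

    def test_best_checkpoint_restored(self):
        state = {"value": 0}
        vals = [3.0, 1.0, 2.0, 4.0]
        epoch = {"i": -1}

        def val_fn():
            epoch["i"] += 1
            state["value"] = epoch["i"]
            return vals[epoch["i"]]

        restored = {}
        early_stopped_loop(
            n_train=2,
            step_fn=lambda idx: 0.0,
            val_fn=val_fn,
            snapshot_fn=lambda: dict(state),
            restore_fn=lambda s: restored.update(s),
            config=OptimizerConfig(max_epochs=4, patience=10, batch_size=2),
            rng=np.random.default_rng(0),
        )
        assert restored["value"] == 1  # epoch with val loss 1.0
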