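"""Metrics, interval loss, split arithmetic, and the seeded training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsevit import HRTriple, dataset_split_shares, loss_variant_b, mae, rmse
from pulsevit.train_eval import EvalBatch, TrainConfig, train

batches = st.integers(1, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(30.0, 240.0), min_size=n, max_size=n),
        st.lists(st.floats(0.0, 300.0), min_size=n, max_size=n),
    )
)


class TestMetrics:
    def test_perfect_predictions_score_zero(self):
        t = np.array([60.0, 75.0, 90.0])
        assert mae(t, t) == 0.0 and rmse(t, t) == 0.0

    def test_worked_arithmetic(self):
        t, p = np.array([70.0, 80.0]), np.array([73.0, 76.0])
        assert mae(t, p) == pytest.approx(3.5)
        assert rmse(t, p) == pytest.approx(np.sqrt(12.5))

    @given(batches)
    @settings(max_examples=200, deadline=None)
    def test_match_loop_oracles_and_rmse_dominates_mae(self, tp):
        truths, preds = np.array(tp[0]), np.array(tp[1])
        loop_mae = sum(abs(a - b) for a, b in zip(truths, preds)) / len(truths)
        loop_rmse = (sum((a - b) ** 2 for a, b in zip(truths, preds)) / len(truths)) ** 0.5
        assert mae(truths, preds) == pytest.approx(loop_mae, rel=1e-12)
        assert rmse(truths, preds) == pytest.approx(loop_rmse, rel=1e-12)
        assert rmse(truths, preds) >= mae(truths, preds) - 1e-12

    def test_permutation_invariance(self, rng):
        t, p = rng.uniform(40, 180, 20), rng.uniform(40, 180, 20)
        perm = rng.permutation(20)
        assert mae(t, p) == pytest.approx(mae(t[perm], p[perm]))
        assert rmse(t, p) == pytest.approx(rmse(t[perm], p[perm]))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            EvalBatch(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            mae(np.array([1.0, 2.0]), np.array([1.0]))


class TestIntervalLoss:
    def test_zero_when_prediction_equals_label(self):
        t = HRTriple(60.0, 80.0, 70.0)
        assert loss_variant_b(t, t) == 0.0

    def test_worked_arithmetic(self):
        pred, lab = HRTriple(60.0, 80.0, 70.0), HRTriple(62.0, 78.0, 71.0)
        assert loss_variant_b(pred, lab) == pytest.approx(5.0 / 3.0)

    @given(st.lists(st.floats(-200, 400), min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_matches_loop_computation(self, vals):
        p, t = np.array(vals[:3]), np.array(vals[3:])
        loop = sum(abs(a - b) for a, b in zip(p, t)) / 3.0
        assert loss_variant_b(p, t) == pytest.approx(loop, rel=1e-12, abs=1e-12)

    def test_invariant_to_head_permutation(self, rng):
        heads = rng.uniform(40, 180, (5, 3))
        label = np.array([60.0, 90.0, 75.0])
        base = loss_variant_b(heads.mean(axis=0), label)
        shuffled = loss_variant_b(heads[rng.permutation(5)].mean(axis=0), label)
        assert base == pytest.approx(shuffled)


class TestSplitShares:
    def test_published_video_counts_reproduce_printed_shares(self):
        shares = dataset_split_shares([724, 276, 358])
        assert np.round(shares, 2).tolist() == [53.31, 20.32, 26.36]

    def test_validation(self):
        with pytest.raises(ValueError):
            dataset_split_shares([0, 0])


class TestTrainConfig:
    def test_learning_rate_range_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.5)
        TrainConfig(learning_rate=1e-6)
        TrainConfig(learning_rate=0.0)  # degenerate no-update case allowed

    def test_stride_defaults_to_window_length(self):
        assert TrainConfig(window_length=10).stride == 10


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self, micro_manifest, tmp_path):
        cfg = TrainConfig(learning_rate=0.0, epochs=2, seed=1, preset="tiny",
                          batch_size=4, val_fraction=0.5)
        _, log = train(micro_manifest, cfg, tmp_path / "lr0")
        assert log["val_mae"].nunique() == 1
        # per-window losses are frozen; epoch means differ only by the
        # regrouping of the ragged final batch under reshuffling
        assert np.allclose(log["train_loss"], log["train_loss"].iloc[0], rtol=1e-4)

    def test_loss_decreases_on_micro_fixture(self, micro_manifest, tmp_path):
        cfg = TrainConfig(learning_rate=1e-3, epochs=6, seed=2, preset="tiny",
                          batch_size=4, val_fraction=0.5, head_steps=0)
        _, log = train(micro_manifest, cfg, tmp_path / "run")
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_staged_head_phase_logs_and_improves(self, micro_manifest, tmp_path):
        cfg = TrainConfig(learning_rate=3e-3, epochs=1, seed=2, preset="tiny",
                          batch_size=4, val_fraction=0.5,
                          head_steps=300, head_batch=8, head_log_every=100)
        _, log = train(micro_manifest, cfg, tmp_path / "staged")
        assert len(log) == 4  # 3 head-phase rows + 1 fine-tune epoch
        assert log["train_loss"].iloc[2] < log["train_loss"].iloc[0]

    def test_same_seed_reproduces_metric_log_bitwise(self, micro_manifest, tmp_path):
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=3, preset="tiny",
                          batch_size=4, val_fraction=0.5, head_steps=0)
        _, log1 = train(micro_manifest, cfg, tmp_path / "a")
        _, log2 = train(micro_manifest, cfg, tmp_path / "b")
        assert log1.equals(log2)

    def test_variant_a_trains_and_logs(self, micro_manifest, tmp_path):
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=4, preset="tiny",
                          batch_size=4, val_fraction=0.5, variant="A")
        ckpt, log = train(micro_manifest, cfg, tmp_path / "va")
        assert list(log.columns) == ["epoch", "train_loss", "val_mae", "val_rmse"]
        assert np.isfinite(log[["train_loss", "val_mae", "val_rmse"]]).all().all()
        assert ckpt.exists()


class TestSweep:
    def test_window_length_grid_produces_table(self, micro_manifest, tmp_path):
        from pulsevit.train_eval import sweep
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=5, preset="tiny",
                          batch_size=4, val_fraction=0.5, head_steps=0)
        table = sweep(micro_manifest, [5, 15], cfg, tmp_path / "sw")
        assert list(table.columns) == ["setting", "mae", "rmse"]
        assert table["setting"].tolist() == [5, 15]
        assert np.isfinite(table[["mae", "rmse"]]).all().all()
        assert (tmp_path / "sw" / "sweep.csv").exists()

    def test_empty_grid_rejected(self, micro_manifest, tmp_path):
        from pulsevit.train_eval import sweep
        with pytest.raises(ValueError):
            sweep(micro_manifest, [], TrainConfig(), tmp_path / "sw2")
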