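"""Pseudo-label assembly, loss arithmetic, and the optimization loop."""

import numpy as np
import pytest

from pcleservo import nn
from pcleservo.bis4d import BiS4DConfig, DistanceRegressor
from pcleservo.edd import EDDConfig
from pcleservo.features import FeatureConfig
from pcleservo.scanner import ScannerConfig, generate_dataset
from pcleservo.training import (
    TrainConfig,
    build_examples,
    build_rollout_examples,
    build_stationary_examples,
    cyclic_lr,
    loss_combined,
    loss_mae,
    loss_mape,
    train,
)


@pytest.fixture(scope="module")
def tiny_videos():
    cfg = ScannerConfig(seed=3)
    train_videos, _ = generate_dataset(cfg, 2, 1, seed=3)
    return train_videos


class TestBuildExamples:
    def test_zero_start_yields_optimum_frames_and_zero_labels(self, clean_video):
        examples = build_examples([clean_video], EDDConfig(), 400, seed=0)
        zero_starts = [ex for ex in examples if ex.labels[0] == 0.0]
        assert zero_starts, "uniform grid sampling produced no zero start in 400 draws"
        for ex in zero_starts:
            assert np.all(ex.labels == 0.0)
            assert all(f.position == 0.0 for f in ex.frames)

    def test_deterministic_for_fixed_seed(self, tiny_videos):
        a = build_examples(tiny_videos, EDDConfig(), 5, seed=1)
        b = build_examples(tiny_videos, EDDConfig(), 5, seed=1)
        assert all(np.array_equal(x.labels, y.labels) for x, y in zip(a, b))

    def test_counts_and_grid_membership(self, tiny_videos):
        examples = build_examples(tiny_videos, EDDConfig(), 25, seed=2)
        assert len(examples) == 50
        for ex in examples:
            np.testing.assert_allclose(np.asarray(ex.labels) % 5.0, 0.0, atol=1e-9)
            assert np.all(np.abs(ex.labels) <= 400.0)
            np.testing.assert_array_equal([f.position for f in ex.frames], ex.labels)

    def test_auxiliary_builders_label_true_positions(self, tiny_videos):
        for builder in (build_stationary_examples, build_rollout_examples):
            examples = builder(tiny_videos, 3, seed=4)
            for ex in examples:
                np.testing.assert_array_equal([f.position for f in ex.frames], ex.labels)

    def test_empty_videos_rejected(self):
        with pytest.raises(ValueError):
            build_examples([], EDDConfig(), 1, seed=0)


class TestLosses:
    def test_mae_hand_examples(self):
        assert loss_mae([10, 20], [12, 18]) == 2.0
        assert loss_mae([3.0, -1.0], [3.0, -1.0]) == 0.0
        assert loss_mae([-5, 5], [0, 0]) == 5.0

    def test_mape_hand_examples(self):
        assert loss_mape([10, 20], [12, 18]) == pytest.approx(15.0)
        assert loss_mape([0, 10], [3, 10]) == 0.0  # zero-label term dropped
        assert loss_mape([4.0, 8.0], [4.0, 8.0]) == 0.0

    def test_mape_all_zero_labels(self):
        assert loss_mape([0.0, 0.0], [5.0, -3.0]) == 0.0

    def test_mape_epsilon_variant(self):
        # epsilon denominator keeps zero-label terms with a floored weight
        assert loss_mape([0.0], [1.0], epsilon=2.0) == pytest.approx(50.0)

    def test_combined_hand_example(self):
        assert loss_combined([10, 20], [12, 18]) == pytest.approx(8.5)
        assert loss_combined([10, 20], [12, 18], "MAE") == 2.0
        assert loss_combined([10, 20], [12, 18], "MAPE") == pytest.approx(15.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            loss_combined([1.0], [1.0], "huber")

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=12) * 100, rng.normal(size=12) * 100
        t = loss_combined(y, nn.Tensor(yhat))
        assert float(t.data) == pytest.approx(loss_combined(y, yhat))

    def test_likelihood_mode(self):
        y = nn.Tensor([1.0, 2.0])
        yhat = nn.Tensor([1.0, 2.0])
        log_var = nn.Tensor([0.0, 0.0])
        out = loss_combined(y, yhat, "likelihood", log_var=log_var)
        np.testing.assert_allclose(float(out.data), 0.0, atol=1e-12)

    def test_loss_gradients_flow(self):
        yhat = nn.Tensor([5.0, 15.0], requires_grad=True)
        loss = loss_combined(np.array([10.0, 20.0]), yhat)
        loss.backward()
        assert yhat.grad is not None and np.all(yhat.grad != 0)


class TestSchedule:
    def test_triangular_endpoints(self):
        cfg = TrainConfig()
        assert cyclic_lr(0, cfg) == cfg.lr_min
        assert cyclic_lr(5, cfg) == cfg.lr_max
        assert cyclic_lr(10, cfg) == cfg.lr_min
        assert cyclic_lr(15, cfg) == cfg.lr_max

    def test_midpoint(self):
        cfg = TrainConfig(lr_min=0.0, lr_max=1.0)
        assert cyclic_lr(2, cfg) == pytest.approx(0.4)
        assert cyclic_lr(8, cfg) == pytest.approx(0.4)


class TestTrainLoop:
    def _model(self, seed=0, n_layers=1):
        return DistanceRegressor(
            FeatureConfig(seed=seed),
            BiS4DConfig(seed=seed, n_layers=n_layers, model_dim=32, state_size=4),
        )

    def test_reproducible_loss_trajectory(self, tiny_videos):
        examples = build_examples(tiny_videos, EDDConfig(), 4, seed=5)
        cfg = TrainConfig(epochs=2, seed=9, single_frame_batch=8)
        r1 = train(self._model(1, 1), examples, cfg, videos=tiny_videos)
        r2 = train(self._model(1, 1), examples, cfg, videos=tiny_videos)
        assert r1.epoch_losses == r2.epoch_losses

    def test_loss_improves_over_training(self, tiny_videos):
        examples = build_examples(tiny_videos, EDDConfig(), 20, seed=6)
        cfg = TrainConfig(epochs=6, seed=1, single_frame_batch=16)
        result = train(self._model(2, 1), examples, cfg, videos=tiny_videos)
        assert result.epoch_losses[-1] < result.epoch_losses[0]

    def test_finetune_freezes_spatial_encoder(self, tiny_videos):
        examples = build_examples(tiny_videos, EDDConfig(), 4, seed=7)
        model = self._model(3, 1)
        before = [p.data.copy() for p in model.extractor.spatial_parameters()]
        eps_before = model.extractor.eps.w.data.copy()
        train(
            model,
            examples,
            TrainConfig(epochs=1, seed=2, finetune=True, single_frame_batch=8),
            videos=tiny_videos,
        )
        for old, p in zip(before, model.extractor.spatial_parameters()):
            np.testing.assert_array_equal(old, p.data)
        assert np.any(eps_before != model.extractor.eps.w.data)  # ε keeps training

    def test_finetune_requires_single_layer(self, tiny_videos):
        examples = build_examples(tiny_videos, EDDConfig(), 2, seed=8)
        with pytest.raises(ValueError):
            train(
                self._model(4, n_layers=3),
                examples,
                TrainConfig(epochs=1, finetune=True),
                videos=tiny_videos,
            )

    def test_empty_dataset_rejected(self, tiny_videos):
        with pytest.raises(ValueError):
            train(self._model(5, 1), [], TrainConfig(epochs=1), videos=tiny_videos)
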