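"""Bidirectional S4D network: layer algebra, stack composition, regressor."""

import numpy as np
import pytest

from pcleservo import nn
from pcleservo.bis4d import (
    BiS4DConfig,
    BiS4DLayer,
    BiS4DStack,
    DistanceRegressor,
    bis4d_layer,
    bis4d_stack,
    regress_distances,
)
from pcleservo.features import FeatureConfig
from pcleservo.s4d import apply_conv


@pytest.fixture
def config():
    return BiS4DConfig(n_layers=2, model_dim=6, state_size=4, seed=0)


class TestLayer:
    def test_length_one_input_is_well_defined(self, config):
        layer = BiS4DLayer(config, seed=1)
        out = bis4d_layer(np.ones((1, 6)), layer)
        assert out.shape == (1, 6)
        assert np.all(np.isfinite(out))

    def test_zero_input_zero_bias_gives_zero_output(self, config):
        layer = BiS4DLayer(config, seed=2)
        layer.proj.b.data[:] = 0.0
        out = bis4d_layer(np.zeros((5, 6)), layer)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_palindrome_symmetry_with_tied_branches(self):
        cfg = BiS4DConfig(n_layers=1, model_dim=3, state_size=4, combine_mode="sum", seed=0)
        layer = BiS4DLayer(cfg, seed=3)
        # copy forward branch parameters into the backward branch
        layer.bwd.load_state_arrays(layer.fwd.state_arrays())
        layer.bwd._A = layer.fwd._A.copy()
        layer.bwd._B = layer.fwd._B.copy()
        layer.bwd._log_dt = layer.fwd._log_dt.copy()
        layer.bwd._basis_cache.clear()
        rng = np.random.default_rng(0)
        half = rng.standard_normal((3, 3))
        u = np.concatenate([half, half[::-1]])  # palindromic sequence
        out = bis4d_layer(u, layer)
        np.testing.assert_allclose(out, out[::-1], atol=1e-10)

    def test_forward_branch_matches_s4d_core(self, config):
        """The trainable branch reproduces the functional reference path."""
        layer = BiS4DLayer(config, seed=4)
        rng = np.random.default_rng(1)
        u = rng.standard_normal((7, 6))
        got = layer.fwd(nn.Tensor(u[None])).data[0]
        want = apply_conv(layer.fwd.to_layer_params(), u)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestStack:
    def test_single_layer_stack_matches_manual_block(self, config):
        cfg = BiS4DConfig(**{**vars(config), "n_layers": 1})
        stack = BiS4DStack(cfg)
        rng = np.random.default_rng(2)
        u = rng.standard_normal((5, 6))
        manual = stack.blocks[0](nn.Tensor(u[None]))
        manual = stack.final_norm(manual).data[0]
        np.testing.assert_allclose(bis4d_stack(u, stack), manual, atol=1e-12)

    def test_two_layer_stack_composes_blocks(self, config):
        stack = BiS4DStack(config)
        rng = np.random.default_rng(3)
        u = rng.standard_normal((4, 6))
        h = stack.blocks[0](nn.Tensor(u[None]))
        h = stack.blocks[1](h)
        want = stack.final_norm(h).data[0]
        np.testing.assert_allclose(bis4d_stack(u, stack), want, atol=1e-12)

    def test_zeroed_layers_reduce_to_residual_identity(self, config):
        stack = BiS4DStack(config)
        for block in stack.blocks:
            for p in block.layer.parameters():
                p.data[:] = 0.0
        stack.final_norm.g.data[:] = 1.0
        rng = np.random.default_rng(4)
        u = rng.standard_normal((5, 6))
        # with zeroed layers only the residual path and final norm remain
        mu = u.mean(axis=-1, keepdims=True)
        expected = (u - mu) / np.sqrt(u.var(axis=-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(bis4d_stack(u, stack), expected, atol=1e-8)

    def test_length_equivariance(self, config):
        stack = BiS4DStack(config)
        rng = np.random.default_rng(5)
        for L in (1, 2, 5, 10, 20):
            out = bis4d_stack(rng.standard_normal((L, 6)), stack)
            assert out.shape == (L, 6)


@pytest.fixture(scope="module")
def model():
    return DistanceRegressor(
        FeatureConfig(seed=0), BiS4DConfig(n_layers=2, model_dim=32, state_size=4, seed=0)
    )


class TestRegressor:
    def test_singleton_sequence_gives_single_scalar(self, model, noisy_video):
        pred = regress_distances([noisy_video.frames[0]], model)
        assert pred.distances.shape == (1,)

    def test_direction_sensitivity(self, model, noisy_video):
        """With untied branch parameters the model is genuinely
        bidirectional: reversing the input does not reverse the output."""
        frames = noisy_video.frames[0:100:10]
        fwd = model.predict_sequence(frames)
        rev = model.predict_sequence(frames[::-1])
        assert not np.allclose(fwd, rev[::-1], atol=1e-6)

    def test_evaluation_determinism(self, model, noisy_video):
        frames = noisy_video.frames[0:50:10]
        a = model.predict_sequence(frames)
        b = model.predict_sequence(frames)
        np.testing.assert_array_equal(a, b)

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            regress_distances([], model)

    def test_checkpoint_roundtrip(self, model, noisy_video, tmp_path):
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = DistanceRegressor.load(path)
        frames = noisy_video.frames[0:30:10]
        np.testing.assert_allclose(
            model.predict_sequence(frames), loaded.predict_sequence(frames), atol=1e-12
        )

    def test_checkpoint_config_mismatch_rejected(self, model, tmp_path):
        import json

        import numpy as np

        path = tmp_path / "ckpt.npz"
        model.save(path)
        data = dict(np.load(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["hash"] = "deadbeefdeadbeef"
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError):
            DistanceRegressor.load(path)
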