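"""Bidirectional S4D network and the per-frame distance regressor.

A bidirectional layer runs two independent diagonal state-space banks over
the feature sequence, one in the given order and one over the reversed
sequence (whose output is reversed back), and combines the two branch
outputs — by channel concatenation plus a trained projection back to the
model width (default), or by summation (ablation).  Blocks are stacked with
pre-layer-normalization residual connections; a per-frame affine head maps
the final representation to a signed distance in µm.

Inside the trainable network the state dynamics (A, B, timescales) of every
S4D bank stay frozen at their S4D-Lin initialization; the complex output
maps C, the skips D and all projections are trained.  The kernel is linear
in C, which keeps the backward pass a single Vandermonde contraction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from . import s4d as s4d_core
from .features import FeatureConfig, FeatureExtractor, FeatureSequence, featurize_sequence
from .scanner import Frame

__all__ = [
    "BiS4DConfig",
    "DistancePrediction",
    "S4DModule",
    "BiS4DLayer",
    "BiS4DStack",
    "DistanceRegressor",
    "bis4d_layer",
    "bis4d_stack",
    "regress_distances",
]

# Network outputs are trained on targets scaled to ~[-1, 1]; the head output
# is multiplied by this constant to express distances in µm.
OUTPUT_SCALE_UM = 400.0


@dataclass
class BiS4DConfig:
    n_layers: int = 3
    model_dim: int = 32
    state_size: int = 8
    combine_mode: str = "concat_project"  # or "sum"
    dropout_rate: float = 0.0
    dt_min: float = 1e-3
    dt_max: float = 1e-1
    seed: int = 0

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.combine_mode not in ("concat_project", "sum"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class DistancePrediction:
    """Per-frame signed distance predictions (µm), aligned with the input."""

    distances: np.ndarray
    positions: list[float | None]


class S4DModule(nn.Module):
    """One trainable S4D bank (H channels); dynamics frozen, C and D trained."""

    def __init__(self, channels: int, state_size: int, dt_min: float, dt_max: float, seed: int):
        base = s4d_core.init_s4d(state_size, channels, dt_min=dt_min, dt_max=dt_max, seed=seed)
        self._A = base.A
        self._B = base.B
        self._log_dt = base.log_dt
        self.c_re = nn.Tensor(base.C.real, requires_grad=True)
        self.c_im = nn.Tensor(base.C.imag, requires_grad=True)
        self.d = nn.Tensor(base.D, requires_grad=True)
        self._basis_cache: dict[int, np.ndarray] = {}

    def to_layer_params(self) -> s4d_core.S4DLayerParams:
        return s4d_core.S4DLayerParams(
            A=self._A.copy(),
            B=self._B.copy(),
            C=self.c_re.data + 1j * self.c_im.data,
            D=self.d.data.copy(),
            log_dt=self._log_dt.copy(),
        )

    def _basis(self, length: int) -> np.ndarray:
        if length not in self._basis_cache:
            self._basis_cache[length] = s4d_core.s4d_basis(self.to_layer_params(), length)
        return self._basis_cache[length]

    def __call__(self, u: nn.Tensor) -> nn.Tensor:
        """u: [B, L, H] -> [B, L, H] (causal)."""
        return nn.s4d_causal_conv(u, self.c_re, self.c_im, self.d, self._basis(u.shape[1]))


class BiS4DLayer(nn.Module):
    """Forward + backward S4D branches with a combine/resize step."""

    def __init__(self, config: BiS4DConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.fwd = S4DModule(config.model_dim, config.state_size, config.dt_min, config.dt_max, seed=seed * 2 + 1)
        self.bwd = S4DModule(config.model_dim, config.state_size, config.dt_min, config.dt_max, seed=seed * 2 + 2)
        self.combine_mode = config.combine_mode
        if config.combine_mode == "concat_project":
            self.proj = nn.Linear(2 * config.model_dim, config.model_dim, rng=rng)

    def __call__(self, u: nn.Tensor) -> nn.Tensor:
        yf = nn.gelu(self.fwd(u))
        yb = nn.flip(nn.gelu(self.bwd(nn.flip(u, axis=1))), axis=1)
        if self.combine_mode == "sum":
            return yf + yb
        return self.proj(nn.concat([yf, yb], axis=-1))


class BiS4DBlock(nn.Module):
    """Pre-LN residual wrapper around one bidirectional layer."""

    def __init__(self, config: BiS4DConfig, seed: int):
        self.norm = nn.LayerNorm(config.model_dim)
        self.layer = BiS4DLayer(config, seed)

    def __call__(self, u: nn.Tensor) -> nn.Tensor:
        return u + self.layer(self.norm(u))


class BiS4DStack(nn.Module):
    """n_layers sequential bidirectional blocks plus a final normalization."""

    def __init__(self, config: BiS4DConfig):
        config.validate()
        self.config = config
        self.blocks = [BiS4DBlock(config, seed=config.seed * 101 + i) for i in range(config.n_layers)]
        self.final_norm = nn.LayerNorm(config.model_dim)
        self.training = False
        self._drop_rng = np.random.default_rng(config.seed + 55)

    def __call__(self, u: nn.Tensor) -> nn.Tensor:
        p = self.config.dropout_rate
        for block in self.blocks:
            u = block(u)
            if self.training and p > 0:
                mask = self._drop_rng.random(u.shape) >= p
                u = u * nn.Tensor(mask / (1.0 - p))
        return self.final_norm(u)


# -- spec-level functional surface ------------------------------------------

def bis4d_layer(u: np.ndarray, layer: BiS4DLayer) -> np.ndarray:
    """Apply one bidirectional layer to a [L, H] or [B, L, H] sequence."""
    arr = np.asarray(u, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    out = layer(nn.Tensor(arr)).data
    return out[0] if squeeze else out


def bis4d_stack(u: np.ndarray, stack: BiS4DStack) -> np.ndarray:
    """Apply the full residual stack to a [L, H] or [B, L, H] sequence."""
    arr = np.asarray(u, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    out = stack(nn.Tensor(arr)).data
    return out[0] if squeeze else out


class SingleFrameHead(nn.Module):
    """Per-frame regressor used by the guided controller (no temporal context).

    Operates on the explicit spectral band energies and intensity moments
    only — the channels whose across-sample variability the training loop
    randomizes — so its calibration cannot silently attach to the
    appearance of the handful of training textures.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.l1 = nn.Linear(n_in, hidden, rng=rng)
        self.l2 = nn.Linear(hidden, hidden, rng=rng)
        self.l3 = nn.Linear(hidden, 1, rng=rng)

    def __call__(self, f: nn.Tensor) -> nn.Tensor:
        return self.l3(nn.gelu(self.l2(nn.gelu(self.l1(f)))))


class DistanceRegressor(nn.Module):
    """Full model: feature extractor + BiS4D stack + regression heads.

    ``predict_sequence`` returns one signed distance per input frame;
    ``predict_single`` is the per-frame path used by the guided controller
    during the first scanning steps.
    """

    def __init__(self, feature_config: FeatureConfig, bis4d_config: BiS4DConfig):
        bis4d_config.validate()
        if feature_config.fused_dim != bis4d_config.model_dim:
            raise ValueError("fused feature dim must equal the BiS4D model_dim")
        self.feature_config = feature_config
        self.bis4d_config = bis4d_config
        rng = np.random.default_rng(bis4d_config.seed + 7)
        self.extractor = FeatureExtractor(feature_config)
        self.stack = BiS4DStack(bis4d_config)
        self.head = nn.Linear(bis4d_config.model_dim, 1, rng=rng)
        self.single_head = SingleFrameHead(feature_config.n_bands + 2, 32, rng=rng)
        self.log_var_head = nn.Linear(bis4d_config.model_dim, 1, rng=rng)

    # -- trainable batched paths ------------------------------------------
    def forward_features(self, feats: nn.Tensor) -> nn.Tensor:
        """feats [B, L, F] -> predicted distances [B, L] (µm)."""
        h = self.stack(feats)
        return nn.reshape(self.head(h), h.shape[:2]) * OUTPUT_SCALE_UM

    def forward_log_var(self, feats: nn.Tensor) -> nn.Tensor:
        h = self.stack(feats)
        return nn.reshape(self.log_var_head(h), h.shape[:2])

    def forward_single(self, spectral: nn.Tensor) -> nn.Tensor:
        """spectral [B, n_bands + 2] (bands + moments) -> distances [B] (µm)."""
        return nn.reshape(self.single_head(spectral), (spectral.shape[0],)) * OUTPUT_SCALE_UM

    # -- inference conveniences -------------------------------------------
    def frame_inputs(self, frame: Frame):
        """Cacheable per-frame inputs (conv features, bands, raw stats)."""
        return self.extractor.frame_inputs(frame)

    def predict_from_inputs(self, inputs: list) -> np.ndarray:
        """Predict distances for an acquisition window of cached inputs."""
        feats = self.extractor.window_features(inputs)
        return self.predict_from_features(feats)

    def predict_from_features(self, feats: np.ndarray) -> np.ndarray:
        return self.forward_features(nn.Tensor(np.asarray(feats)[None])).data[0]

    def predict_sequence(self, frames: list[Frame]) -> np.ndarray:
        seq = featurize_sequence(frames, self.extractor)
        return self.predict_from_features(seq.vectors)

    def predict_single(self, frame: Frame) -> float:
        return self.predict_single_from_inputs(self.frame_inputs(frame))

    def predict_single_from_inputs(self, inputs) -> float:
        _, freq, stats = inputs
        spectral = np.concatenate([freq, stats[2:4]])[None]
        return float(self.forward_single(nn.Tensor(spectral)).data[0])

    # -- checkpointing ------------------------------------------------------
    def config_dict(self) -> dict:
        return {"features": asdict(self.feature_config), "bis4d": asdict(self.bis4d_config)}

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        arrays = self.state_arrays()
        meta = json.dumps({"config": self.config_dict(), "hash": self.config_hash()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DistanceRegressor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(
                FeatureConfig(**meta["config"]["features"]),
                BiS4DConfig(**meta["config"]["bis4d"]),
            )
            if model.config_hash() != meta["hash"]:
                raise ValueError("checkpoint config hash mismatch")
            model.load_state_arrays({k: v for k, v in data.items() if k != "__meta__"})
        # drop stale kernel bases built from the initialization-time C
        for block in model.stack.blocks:
            block.layer.fwd._basis_cache.clear()
            block.layer.bwd._basis_cache.clear()
        return model


def regress_distances(
    sequence: FeatureSequence | list[Frame],
    model: DistanceRegressor,
) -> DistancePrediction:
    """Predict one signed probe-tissue distance (µm) per input frame."""
    if isinstance(sequence, FeatureSequence):
        if len(sequence) == 0:
            raise ValueError("cannot regress an empty sequence")
        distances = model.predict_from_features(sequence.vectors)
        positions = sequence.positions
    else:
        if len(sequence) == 0:
            raise ValueError("cannot regress an empty sequence")
        distances = model.predict_sequence(sequence)
        positions = [f.position for f in sequence]
    return DistancePrediction(distances=distances, positions=positions)
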