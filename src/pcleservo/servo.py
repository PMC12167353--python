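"""Closed-loop probe positioning and the K-step evaluation protocol.

Inference alternates acquire -> predict -> move for K steps.  The first
``N_S`` steps use the guided controller: a single-frame regressor with no
temporal context, which moves the probe into the vicinity of the working
band quickly.  From step N_S onward the sequential model predicts from the
last ``L_max`` acquired frames (all of them when fewer are available), and
the prediction aligned with the newest frame commands the move.

The position update is P <- P - d_pred: the prediction estimates the signed
offset from the optimal scanning position, so subtracting it drives the
probe toward 0.  Commanded positions are snapped to the 5 µm grid before
acquisition (the environment only records grid frames) and clamped to the
±400 µm sweep range.

Convergence is retrospective: the convergence step of a run is the first
index from which the probe stays inside the working band (half-width 35 µm
by default, the magnitude of the probe's specified working range) until the
end of the run.  Metrics: MAE_1st (first prediction error), ACC_dir (sign
agreement of the first prediction), MAE^C (mean |position| after
convergence), W^B (max-min of post-convergence positions), BM (mean
sharpness of post-convergence frames; variance of the Laplacian, normalized
per video so the sharpest sweep frame scores 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import laplace

from .scanner import Frame, SyntheticVideo

__all__ = [
    "ControllerConfig",
    "ServoRun",
    "MetricsReport",
    "step",
    "run_kstep",
    "detect_convergence",
    "compute_metrics",
    "blur_metric",
    "laplacian_variance",
    "OracleRegressor",
]


@dataclass
class ControllerConfig:
    L_max: int = 10
    N_S: int = 3                      # guided-controller steps; 0 disables it
    K: int = 20
    working_band_halfwidth: float = 35.0
    stop_on_stabilize: bool = False
    position_limit: float = 400.0
    grid_step: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.L_max < 1:
            raise ValueError("L_max must be >= 1")
        if not (0 <= self.N_S < self.K):
            raise ValueError("require 0 <= N_S < K")
        if self.working_band_halfwidth < 0:
            raise ValueError("working_band_halfwidth must be nonnegative")


@dataclass
class ServoRun:
    """History of one closed-loop run; positions has one more entry than
    predictions (position after the last move is recorded)."""

    P0: float
    positions: list[float] = field(default_factory=list)
    predictions: list[float] = field(default_factory=list)
    used_single_frame: list[bool] = field(default_factory=list)
    frames: list[Frame] = field(default_factory=list)
    clamp_events: list[int] = field(default_factory=list)
    converged_at: int | None = None
    env: SyntheticVideo | None = None
    _feat_cache: list[np.ndarray] = field(default_factory=list, repr=False)


def _snap(position: float, config: ControllerConfig) -> float:
    g = config.grid_step
    snapped = round(position / g) * g
    return float(np.clip(snapped, -config.position_limit, config.position_limit))


def laplacian_variance(pixels: np.ndarray) -> float:
    """Unnormalized sharpness: variance of the Laplacian response."""
    if not np.all(np.isfinite(pixels)):
        raise ValueError("frame contains non-finite pixels")
    return float(laplace(np.asarray(pixels, float)).var())


_BM_NORM_CACHE: dict[int, float] = {}


def blur_metric(frame: Frame, video: SyntheticVideo) -> float:
    """Sharpness in [0, 1]: Laplacian variance over the video's sweep maximum."""
    key = id(video)
    if key not in _BM_NORM_CACHE:
        _BM_NORM_CACHE[key] = max(laplacian_variance(f.pixels) for f in video.frames)
    norm = _BM_NORM_CACHE[key]
    if norm <= 0:
        return 0.0
    return min(laplacian_variance(frame.pixels) / norm, 1.0)


def step(state: ServoRun, env: SyntheticVideo, model, config: ControllerConfig) -> ServoRun:
    """Acquire a frame at the current position, predict, move."""
    config.validate()
    if model is None:
        raise RuntimeError("servo step requires an initialized model")
    k = len(state.predictions)
    if not state.positions:
        state.positions.append(_snap(state.P0, config))
    pos = _snap(state.positions[-1], config)
    frame = env.frame_at(pos)
    state.frames.append(frame)

    use_single = k < config.N_S
    has_cache = hasattr(model, "frame_inputs")
    if has_cache:
        state._feat_cache.append(model.frame_inputs(frame))
    if use_single:
        if has_cache:
            d_pred = float(model.predict_single_from_inputs(state._feat_cache[-1]))
        else:
            d_pred = float(model.predict_single(frame))
    elif has_cache:
        d_pred = float(model.predict_from_inputs(state._feat_cache[-config.L_max :])[-1])
    else:  # oracle-style models expose predict_sequence only
        window = state.frames[-config.L_max :]
        d_pred = float(model.predict_sequence(window)[-1])

    state.predictions.append(d_pred)
    state.used_single_frame.append(use_single)
    new_pos = pos - d_pred
    clamped = float(np.clip(new_pos, -config.position_limit, config.position_limit))
    if clamped != new_pos:
        state.clamp_events.append(k)
    state.positions.append(clamped)
    return state


def run_kstep(env: SyntheticVideo, model, P0: float, config: ControllerConfig) -> ServoRun:
    """Run the K-step incremental protocol from initial position P0."""
    config.validate()
    if abs(P0) > config.position_limit:
        raise ValueError(f"|P0| must be <= {config.position_limit} µm")
    state = ServoRun(P0=float(P0), env=env)
    for k in range(config.K):
        step(state, env, model, config)
        if (
            config.stop_on_stabilize
            and k >= config.N_S + 2
            and all(abs(p) <= config.working_band_halfwidth for p in state.positions[-3:])
        ):
            break
    state.converged_at = detect_convergence(state, config)
    return state


def detect_convergence(run: ServoRun, config: ControllerConfig) -> int | None:
    """First step index from which |position| stays inside the band."""
    positions = np.asarray(run.positions, float)
    if positions.size < 2:
        raise ValueError("convergence detection needs at least 2 recorded positions")
    inside = np.abs(positions) <= config.working_band_halfwidth
    if not inside[-1]:
        return None
    # last index where the probe was outside the band, +1
    outside = np.nonzero(~inside)[0]
    return int(outside[-1]) + 1 if outside.size else 0


@dataclass
class MetricsReport:
    MAE_1st: float
    ACC_dir: float
    MAE_C_mean: float
    MAE_C_sd: float
    W_B: float
    BM: float
    n_runs: int
    n_converged: int

    def to_dict(self) -> dict:
        return {
            "MAE_1st": self.MAE_1st,
            "ACC_dir": self.ACC_dir,
            "MAE_C_mean": self.MAE_C_mean,
            "MAE_C_sd": self.MAE_C_sd,
            "W_B": self.W_B,
            "BM": self.BM,
            "n_runs": self.n_runs,
            "n_converged": self.n_converged,
        }


def compute_metrics(runs: list[ServoRun], config: ControllerConfig) -> MetricsReport:
    """Convergence and stability metrics over a collection of runs.

    Runs that never converge contribute only to MAE_1st and ACC_dir.  A
    collection with zero converged runs reports W_B = +inf (stability after
    convergence was never achieved) and NaN for the other post-convergence
    means.
    """
    if len(runs) == 0:
        raise ValueError("no runs to evaluate")
    first_err = [abs(r.predictions[0] - r.P0) for r in runs]
    signed = [r for r in runs if r.P0 != 0]
    acc = (
        float(np.mean([np.sign(r.predictions[0]) == np.sign(r.P0) for r in signed]))
        if signed
        else 1.0
    )
    mae_c, widths, bms = [], [], []
    n_conv = 0
    for r in runs:
        s = r.converged_at if r.converged_at is not None else detect_convergence(r, config)
        if s is None:
            continue
        n_conv += 1
        # positions[0] is the externally chosen start, not a controller
        # outcome; stability is measured from the first commanded position
        s = max(s, 1)
        tail = np.asarray(r.positions[s:], float)
        mae_c.append(float(np.mean(np.abs(tail))))
        widths.append(float(tail.max() - tail.min()))
        if r.env is not None:
            post_frames = r.frames[s:]
            if post_frames:
                bms.append(float(np.mean([blur_metric(f, r.env) for f in post_frames])))
    return MetricsReport(
        MAE_1st=float(np.mean(first_err)),
        ACC_dir=acc,
        MAE_C_mean=float(np.mean(mae_c)) if mae_c else float("nan"),
        MAE_C_sd=float(np.std(mae_c)) if mae_c else float("nan"),
        W_B=float(np.mean(widths)) if widths else float("inf"),
        BM=float(np.mean(bms)) if bms else float("nan"),
        n_runs=len(runs),
        n_converged=n_conv,
    )


class OracleRegressor:
    """Perfect regressor reading the true position off the acquired frame.

    Test instrument for the closed-loop bookkeeping: with it, every run
    reaches the optimum in one move and stays there.
    """

    def predict_single(self, frame: Frame) -> float:
        return float(frame.position)

    def predict_sequence(self, frames: list[Frame]) -> np.ndarray:
        return np.array([f.position for f in frames], float)
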