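"""Pseudo-labelled training: example assembly, losses, optimization loop.

Training pairs are built by the EDD planner: a random initial grid position
per example, an exponential approach trajectory snapped to the grid, and the
recorded frames at those positions.  The discretized trajectory positions
play the role of ground-truth distances.

The loss is L_MP = (MAE + MAPE) / 2 by default.  MAPE is undefined at zero
labels — which EDD produces at trajectory tails — so zero-label terms are
excluded from its mean (an epsilon-denominator variant is available).  The
percentage term concentrates accuracy near the optimum, where absolute
errors are small but matter most for holding the probe in its working band.

Optimization is Adam under a triangular cyclic learning rate: lr starts at
lr_min, peaks at lr_max after ``cycle_epochs`` epochs, and descends back
over the next ``cycle_epochs`` (period 2 * cycle_epochs).

Alongside the sequence loss, the single-frame head (used by the guided
controller during the first scanning steps) is trained on the same frames
individually with the same loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .bis4d import DistanceRegressor
from .edd import EDDConfig, plan_trajectory, trajectory_to_frames
from .features import extract_frequency, fusion_extra, global_stats, normalize_pixels
from .scanner import Frame, SyntheticVideo  # noqa: F401  (SyntheticVideo in signatures)

__all__ = [
    "TrainingExample",
    "TrainConfig",
    "build_examples",
    "loss_mae",
    "loss_mape",
    "loss_combined",
    "cyclic_lr",
    "train",
]

LOSS_MODES = ("MAE", "MAPE", "MAE_plus_MAPE", "likelihood")


@dataclass
class TrainingExample:
    frames: list[Frame]
    labels: np.ndarray  # discretized EDD positions, µm
    source_video_id: int


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr_min: float = 1e-5
    lr_max: float = 1e-4
    cycle_epochs: int = 5
    epochs: int = 30
    seed: int = 0
    loss_mode: str = "MAE_plus_MAPE"
    finetune: bool = False           # freeze spatial encoder; 1-layer model
    single_frame_weight: float = 1.0
    # The guided-controller head needs coarse accuracy over the full ±400 µm
    # range, not percentage accuracy near the optimum, so it trains under
    # plain MAE; its gradient also teaches the shared extractor to
    # discriminate positions, which the percentage-weighted sequence loss
    # alone does not do reliably from a cold start.
    single_frame_loss_mode: str = "MAE"
    # Single-frame pairs are drawn uniformly from the recorded sweep grid
    # with the frame's true position as the label (every recorded frame has
    # one), mirroring how a per-frame regressor is trained on this kind of
    # data.  EDD trajectories concentrate near the optimum, which starves the
    # guided controller of large-distance supervision.
    single_frame_batch: int = 32
    # Closed-loop inference feeds the model growing prefixes (early steps)
    # and sliding suffixes (late steps) of the acquisition history, not only
    # full-length planned decays.  Randomly cropping each training batch to a
    # prefix or suffix of its trajectories exposes the model to exactly those
    # window shapes and stops it from keying on a frame's index in the
    # sequence rather than its appearance.
    crop_augmentation: bool = True
    # Per-window constant offsets on the absolute band/statistic channels,
    # drawn with the across-video spread measured on the training videos.
    # Texture confounds are constant within a video and vary across videos;
    # randomizing them in training forces the model onto within-window
    # (texture-invariant) structure, which is what transfers to new tissue.
    domain_randomization: bool = True
    mape_epsilon: float | None = None  # None: drop zero-label terms

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.lr_min < self.lr_max):
            raise ValueError("require 0 < lr_min < lr_max")
        if self.cycle_epochs < 1 or self.epochs < 1:
            raise ValueError("cycle_epochs and epochs must be >= 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}; options: {LOSS_MODES}")


def build_examples(
    videos: list[SyntheticVideo],
    edd_config: EDDConfig,
    n_per_video: int,
    seed: int,
) -> list[TrainingExample]:
    """Sample EDD pseudo-labelled examples: P0 uniform on the grid per example."""
    if len(videos) == 0:
        raise ValueError("no videos to build examples from")
    if n_per_video < 1:
        raise ValueError("n_per_video must be >= 1")
    rng = np.random.default_rng(seed)
    examples = []
    for vid_idx, video in enumerate(videos):
        grid = video.positions()
        for _ in range(n_per_video):
            P0 = float(rng.choice(grid))
            traj = plan_trajectory(P0, edd_config)
            frames = trajectory_to_frames(traj, video)
            examples.append(
                TrainingExample(
                    frames=frames,
                    labels=traj.discretized_positions.copy(),
                    source_video_id=vid_idx,
                )
            )
    return examples


def build_stationary_examples(
    videos: list[SyntheticVideo],
    n_per_video: int,
    seed: int,
    n_steps: int = 10,
    jitter_sd: float = 15.0,
) -> list[TrainingExample]:
    """Stationary/jittered windows labelled by their true grid positions.

    Closed-loop inference can dwell on a nearly constant buffer of frames —
    a state an exponential approach trajectory never produces, since every
    planned decay ends at the optimum.  A model trained on decays alone
    learns that late, mutually similar frames mean "at the optimum" and
    will predict ~0 for any stationary buffer, freezing the probe wherever
    it happens to hover.  These windows (a base grid position plus small
    grid-snapped jitter, labelled with the true recorded positions) teach
    the model to report the actual distance of a stationary buffer.
    """
    if len(videos) == 0:
        raise ValueError("no videos to build examples from")
    rng = np.random.default_rng(seed)
    examples = []
    for vid_idx, video in enumerate(videos):
        grid = video.positions()
        lo, hi = grid.min(), grid.max()
        step = grid[1] - grid[0]
        for _ in range(n_per_video):
            p0 = float(rng.choice(grid))
            jitter = rng.normal(0.0, jitter_sd, size=n_steps)
            jitter[0] = 0.0
            pos = np.clip(p0 + jitter, lo, hi)
            pos = np.round(pos / step) * step
            frames = [video.frame_at(float(p)) for p in pos]
            examples.append(
                TrainingExample(frames=frames, labels=pos.copy(), source_video_id=vid_idx)
            )
    return examples


def build_rollout_examples(
    videos: list[SyntheticVideo],
    n_per_video: int,
    seed: int,
    n_steps: int = 10,
    error_sd: float = 70.0,
) -> list[TrainingExample]:
    """Windows shaped like early closed-loop trajectories, with true labels.

    The first scanning steps are driven by a coarse per-frame regressor, so
    the acquisition buffer the sequential model then receives is a scatter
    of widely spaced positions funnelling toward the optimum — not a planned
    decay.  These examples emulate that shape with a simple error model
    (position update P <- P - (P + e), e ~ N(0, error_sd)) and label every
    frame with its true recorded position.  From such windows the relative
    intensity-moment differences give the frame-to-frame geometry and the
    relative blur profile pins the offset to the optimum, so the model can
    learn to localize the probe in one decisive step — the capability the
    hand-off step depends on.
    """
    if len(videos) == 0:
        raise ValueError("no videos to build examples from")
    rng = np.random.default_rng(seed)
    examples = []
    for vid_idx, video in enumerate(videos):
        grid = video.positions()
        lo, hi = grid.min(), grid.max()
        step = grid[1] - grid[0]
        for _ in range(n_per_video):
            p = float(rng.choice(grid))
            pos = [p]
            for _ in range(n_steps - 1):
                e = rng.normal(0.0, error_sd)
                p = float(np.clip(p - (p + e), lo, hi))
                p = round(p / step) * step
                pos.append(p)
            pos = np.array(pos)
            frames = [video.frame_at(float(q)) for q in pos]
            examples.append(
                TrainingExample(frames=frames, labels=pos.copy(), source_video_id=vid_idx)
            )
    return examples


# -- losses ------------------------------------------------------------------


def loss_mae(y, yhat):
    """Mean absolute error; accepts numpy arrays or autodiff tensors."""
    if isinstance(yhat, nn.Tensor) or isinstance(y, nn.Tensor):
        y, yhat = nn.as_tensor(y), nn.as_tensor(yhat)
        if y.shape != yhat.shape:
            raise ValueError("y and yhat must have the same shape")
        return nn.tmean(nn.absolute(y - yhat))
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    return float(np.mean(np.abs(y - yhat)))


def _mape_weights(y: np.ndarray, epsilon: float | None) -> tuple[np.ndarray, float]:
    """Per-term 1/|denominator| weights and the averaging count."""
    if epsilon is not None:
        return 1.0 / np.maximum(np.abs(y), epsilon), float(y.size)
    nz = y != 0
    weights = np.where(nz, 1.0 / np.where(nz, np.abs(y), 1.0), 0.0)
    return weights, float(max(nz.sum(), 1))


def loss_mape(y, yhat, epsilon: float | None = None):
    """Mean absolute percentage error (percent); zero-label terms dropped."""
    if isinstance(yhat, nn.Tensor) or isinstance(y, nn.Tensor):
        yt, yhat = nn.as_tensor(y), nn.as_tensor(yhat)
        if yt.shape != yhat.shape:
            raise ValueError("y and yhat must have the same shape")
        weights, count = _mape_weights(yt.data, epsilon)
        terms = nn.absolute((yt - yhat) * nn.Tensor(weights))
        return nn.tsum(terms) * (100.0 / count)
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    weights, count = _mape_weights(y, epsilon)
    return float(np.sum(np.abs((y - yhat) * weights)) * 100.0 / count)


def loss_combined(y, yhat, loss_mode: str = "MAE_plus_MAPE", log_var=None, epsilon: float | None = None):
    """Dispatch on loss_mode; MAE_plus_MAPE is (MAE + MAPE) / 2."""
    if loss_mode == "MAE":
        return loss_mae(y, yhat)
    if loss_mode == "MAPE":
        return loss_mape(y, yhat, epsilon=epsilon)
    if loss_mode == "MAE_plus_MAPE":
        mae = loss_mae(y, yhat)
        mape = loss_mape(y, yhat, epsilon=epsilon)
        if isinstance(mae, nn.Tensor):
            return (mae + mape) * 0.5
        return 0.5 * (mae + mape)
    if loss_mode == "likelihood":
        # heteroscedastic Gaussian negative log-likelihood with a predicted
        # per-frame log variance (ablation-only stand-in)
        if log_var is None:
            raise ValueError("likelihood loss requires log_var predictions")
        y, yhat, log_var = nn.as_tensor(y), nn.as_tensor(yhat), nn.as_tensor(log_var)
        sq = nn.power(y - yhat, 2.0)
        return nn.tmean(nn.mul(nn.exp(nn.mul(log_var, -1.0)), sq) * 0.5 + log_var * 0.5)
    raise ValueError(f"unknown loss_mode {loss_mode!r}; options: {LOSS_MODES}")


def cyclic_lr(epoch: int, config: TrainConfig) -> float:
    """Triangular schedule: lr_min at epoch 0, lr_max at epoch cycle_epochs."""
    phase = (epoch / config.cycle_epochs) % 2.0
    tri = phase if phase <= 1.0 else 2.0 - phase
    return config.lr_min + (config.lr_max - config.lr_min) * tri


@dataclass
class TrainResult:
    model: DistanceRegressor
    epoch_losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)


def _frame_arrays(frames: list[Frame], n_bands: int, cache: dict):
    pix, freq, stats = [], [], []
    for f in frames:
        key = id(f)
        if key not in cache:
            p = normalize_pixels(f.pixels)
            cache[key] = (p, extract_frequency(p, n_bands), global_stats(f.pixels))
        c = cache[key]
        pix.append(c[0])
        freq.append(c[1])
        stats.append(c[2])
    return np.stack(pix), np.stack(freq), np.stack(stats)


def _prepare_arrays(model: DistanceRegressor, examples: list[TrainingExample]):
    n_bands = model.feature_config.n_bands
    cache: dict = {}
    X, Q, S, Y = [], [], [], []
    for ex in examples:
        pix, freq, stats = _frame_arrays(ex.frames, n_bands, cache)
        X.append(pix)
        Q.append(freq)
        S.append(stats)
        Y.append(np.asarray(ex.labels, float))
    return np.stack(X), np.stack(Q), np.stack(S), np.stack(Y)


def _across_video_spread(pool_Q, pool_S, pool_Y, pool_vid):
    """Per-channel across-video std of position-conditioned feature means.

    For each |position| bin, average each video's features, then take the
    std across videos; the median over bins estimates how much the absolute
    feature channels shift from one tissue sample to the next.
    """
    bins = np.digitize(np.abs(pool_Y), np.linspace(0, 400, 9)[1:-1])
    vids = np.unique(pool_vid)
    sq, ss = [], []
    for b in np.unique(bins):
        mask_b = bins == b
        mq = np.stack([pool_Q[mask_b & (pool_vid == v)].mean(axis=0) for v in vids])
        ms = np.stack([pool_S[mask_b & (pool_vid == v)].mean(axis=0) for v in vids])
        sq.append(mq.std(axis=0))
        ss.append(ms.std(axis=0))
    return np.median(np.stack(sq), axis=0), np.median(np.stack(ss), axis=0)


def train(
    model: DistanceRegressor,
    examples: list[TrainingExample],
    config: TrainConfig,
    videos: list[SyntheticVideo] | None = None,
) -> TrainResult:
    """Optimize the model in place; returns the per-epoch loss log.

    ``videos`` supplies the frame pool for single-frame (guided controller)
    supervision; when omitted, the example frames themselves are used.
    """
    config.validate()
    if len(examples) == 0:
        raise ValueError("empty training set")
    if config.finetune and model.bis4d_config.n_layers != 1:
        raise ValueError("the fine-tuning regime expects a 1-layer model")

    X, Q, S, Y = _prepare_arrays(model, examples)
    n, L = Y.shape

    pool_X = pool_Q = pool_S = pool_Y = None
    aug_q = aug_s = None
    if config.single_frame_weight > 0 and config.single_frame_batch > 0:
        if videos is not None:
            pool_frames = [f for v in videos for f in v.frames]
            pool_vid = np.repeat(np.arange(len(videos)), [len(v.frames) for v in videos])
        else:
            pool_frames = sorted(
                {id(f): f for ex in examples for f in ex.frames}.values(),
                key=lambda f: f.position,
            )
            pool_vid = None
        pool_X, pool_Q, pool_S = _frame_arrays(pool_frames, model.feature_config.n_bands, {})
        pool_Y = np.array([f.position for f in pool_frames], float)
        if config.domain_randomization and pool_vid is not None and len(videos) > 1:
            aug_q, aug_s = _across_video_spread(pool_Q, pool_S, pool_Y, pool_vid)

    params = model.parameters()
    if config.finetune:
        frozen = {id(p) for p in model.extractor.spatial_parameters()}
        params = [p for p in params if id(p) not in frozen]
    optimizer = nn.Adam(params, lr=config.lr_min)
    rng = np.random.default_rng(config.seed)
    model.stack.training = True

    result = TrainResult(model=model)
    for epoch in range(config.epochs):
        lr = cyclic_lr(epoch, config)
        optimizer.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            bx, bq, bs, by = X[idx], Q[idx], S[idx], Y[idx]
            if config.crop_augmentation:
                mode = rng.integers(0, 3)
                if mode == 1:  # suffix window (late-step inference shape)
                    s = int(rng.integers(1, L - 1))
                    bx, bq, bs, by = bx[:, s:], bq[:, s:], bs[:, s:], by[:, s:]
                elif mode == 2:  # prefix window (early-step inference shape)
                    e = int(rng.integers(2, L + 1))
                    bx, bq, bs, by = bx[:, :e], bq[:, :e], bs[:, :e], by[:, :e]
            B, Lb = by.shape
            if aug_q is not None:
                # per-window constant shifts emulating texture variation;
                # they cancel inside the window-relative differences
                bq = bq + (rng.standard_normal((B, 1, bq.shape[-1])) * aug_q)
                bs = bs + (rng.standard_normal((B, 1, bs.shape[-1])) * aug_s)
            bextra = fusion_extra(bq, bs)  # window-relative + absolute moments
            feats = model.extractor.forward_batch(
                bx.reshape(B * Lb, *bx.shape[2:]), bq.reshape(B * Lb, -1),
                bextra.reshape(B * Lb, -1),
            )
            feats_seq = nn.reshape(feats, (B, Lb, -1))
            preds = model.forward_features(feats_seq)
            if config.loss_mode == "likelihood":
                log_var = model.forward_log_var(feats_seq)
                loss = loss_combined(by, preds, "likelihood", log_var=log_var)
            else:
                loss = loss_combined(by, preds, config.loss_mode, epsilon=config.mape_epsilon)
            if pool_X is not None:
                # single-frame supervision on the spectral channels only
                pick = rng.integers(0, len(pool_Y), size=config.single_frame_batch)
                pq, ps = pool_Q[pick], pool_S[pick]
                if aug_q is not None:
                    pq = pq + rng.standard_normal(pq.shape) * aug_q
                    ps = ps + rng.standard_normal(ps.shape) * aug_s
                spectral = nn.Tensor(np.concatenate([pq, ps[:, 2:4]], axis=-1))
                single = model.forward_single(spectral)
                loss = loss + loss_combined(
                    pool_Y[pick], single, config.single_frame_loss_mode,
                    epsilon=config.mape_epsilon,
                ) * config.single_frame_weight
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        result.epoch_losses.append(epoch_loss / n_batches)
        result.learning_rates.append(lr)
    model.stack.training = False
    return result
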