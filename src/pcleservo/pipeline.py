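"""End-to-end study orchestration: simulate, train, evaluate closed loop.

This module wires the whole method together at desk scale — synthetic sweep
generation, pseudo-labelled training of the 3-layer sequence regressor, the
hierarchical fine-tuning variant, and the K-step closed-loop evaluation —
and returns every headline quantity in one report.  The test suite and the
reproduction script both drive this entry point, so the numbers they print
come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bis4d import BiS4DConfig, DistanceRegressor
from .edd import EDDConfig
from .features import FeatureConfig
from .scanner import ScannerConfig, SyntheticVideo, generate_dataset
from .servo import ControllerConfig, MetricsReport, ServoRun, blur_metric, compute_metrics, run_kstep
from .training import (
    TrainConfig,
    TrainResult,
    build_examples,
    build_rollout_examples,
    build_stationary_examples,
    train,
)

__all__ = ["StudyConfig", "StudyReport", "train_model", "finetune_model", "evaluate_servo", "run_study"]


@dataclass
class StudyConfig:
    """Desk-scale study conditions."""

    seed: int = 0
    n_train_videos: int = 8
    n_test_videos: int = 2
    epochs: int = 30
    finetune_epochs: int = 10
    edd_examples_per_video: int = 161   # one planned approach per grid start
    stationary_examples_per_video: int = 10
    rollout_examples_per_video: int = 10
    p0_min_abs: float = 100.0
    p0_stride: int = 1

    def scanner(self) -> ScannerConfig:
        return ScannerConfig(seed=self.seed)

    def controller(self) -> ControllerConfig:
        return ControllerConfig(seed=self.seed)


@dataclass
class StudyReport:
    metrics: MetricsReport
    convergence_rate: float
    entry_step_385: int | None
    entry_step_m320: int | None
    bm_gain_far_starts: float
    runs: list[ServoRun] = field(repr=False, default_factory=list)
    train_losses: list[float] = field(default_factory=list)


def _derive(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def build_training_set(videos: list[SyntheticVideo], config: StudyConfig):
    """EDD approach trajectories plus a small share of closed-loop-shaped
    windows (stationary hovers and scattered guided-phase rollouts)."""
    edd = build_examples(videos, EDDConfig(), config.edd_examples_per_video, _derive(config.seed, 1))
    stat = build_stationary_examples(
        videos, config.stationary_examples_per_video, _derive(config.seed, 2), jitter_sd=30.0
    )
    roll = build_rollout_examples(
        videos, config.rollout_examples_per_video, _derive(config.seed, 3)
    )
    return edd + stat + roll


def train_model(
    videos: list[SyntheticVideo], config: StudyConfig
) -> tuple[DistanceRegressor, TrainResult]:
    """Train the full 3-layer model under the study conditions."""
    model = DistanceRegressor(
        FeatureConfig(seed=_derive(config.seed, 10)),
        BiS4DConfig(seed=_derive(config.seed, 11)),
    )
    examples = build_training_set(videos, config)
    tcfg = TrainConfig(epochs=config.epochs, seed=_derive(config.seed, 12), single_frame_batch=64)
    result = train(model, examples, tcfg, videos=videos)
    return model, result


def finetune_model(
    base: DistanceRegressor, videos: list[SyntheticVideo], config: StudyConfig
) -> tuple[DistanceRegressor, TrainResult]:
    """Hierarchical fine-tuning: 1 bidirectional layer, frozen extractor.

    The single layer is initialized from the base model's first layer; the
    spatial encoder is copied and frozen while the fusion encoder, the
    remaining layer and the heads keep training.
    """
    small = DistanceRegressor(
        FeatureConfig(**vars(base.feature_config)),
        BiS4DConfig(**{**vars(base.bis4d_config), "n_layers": 1}),
    )
    arrays = base.state_arrays()
    small_arrays = small.state_arrays()
    for key, value in arrays.items():
        if key in small_arrays and small_arrays[key].shape == value.shape:
            small_arrays[key] = value
    small.load_state_arrays(small_arrays)
    examples = build_training_set(videos, config)
    tcfg = TrainConfig(
        epochs=config.finetune_epochs,
        seed=_derive(config.seed, 13),
        finetune=True,
        single_frame_batch=64,
    )
    result = train(small, examples, tcfg, videos=videos)
    return small, result


def evaluate_servo(
    model,
    test_videos: list[SyntheticVideo],
    config: StudyConfig,
    controller: ControllerConfig | None = None,
) -> StudyReport:
    """K-step incremental analysis from every test-grid start position with
    |P0| >= p0_min_abs, plus the trajectory checks for the two showcase
    starts (385 and -320 µm)."""
    ccfg = controller or config.controller()
    runs: list[ServoRun] = []
    for video in test_videos:
        grid = video.positions()[:: config.p0_stride]
        for P0 in grid:
            if abs(P0) < config.p0_min_abs:
                continue
            runs.append(run_kstep(video, model, float(P0), ccfg))
    metrics = compute_metrics(runs, ccfg)
    conv_rate = metrics.n_converged / metrics.n_runs

    def entry_step(P0: float) -> int | None:
        """First step at which the showcase run enters the working band."""
        steps = []
        for video in test_videos:
            run = run_kstep(video, model, P0, ccfg)
            inside = np.nonzero(np.abs(run.positions) <= ccfg.working_band_halfwidth)[0]
            steps.append(int(inside[0]) if inside.size else None)
        if any(s is None for s in steps):
            return None
        return max(steps)  # worst case across the test videos

    bm_gains = []
    for run in runs:
        if abs(run.P0) < 200 or run.converged_at is None or run.env is None:
            continue
        bm0 = blur_metric(run.frames[0], run.env)
        start = min(run.converged_at, len(run.frames) - 1)
        bm_post = np.mean([blur_metric(f, run.env) for f in run.frames[start:]])
        bm_gains.append(float(bm_post - bm0))
    return StudyReport(
        metrics=metrics,
        convergence_rate=conv_rate,
        entry_step_385=entry_step(385.0),
        entry_step_m320=entry_step(-320.0),
        bm_gain_far_starts=float(np.mean(bm_gains)) if bm_gains else float("nan"),
        runs=runs,
        train_losses=[],
    )


def run_study(config: StudyConfig) -> dict:
    """Full pipeline; returns a flat dict of the study's headline numbers."""
    train_videos, test_videos = generate_dataset(
        config.scanner(), config.n_train_videos, config.n_test_videos, config.seed
    )
    model, fit = train_model(train_videos, config)
    report = evaluate_servo(model, test_videos, config)

    fine, _ = finetune_model(model, train_videos, config)
    fine_report = evaluate_servo(fine, test_videos, config)
    untrained = DistanceRegressor(
        FeatureConfig(seed=_derive(config.seed, 20)),
        BiS4DConfig(seed=_derive(config.seed, 21), n_layers=1),
    )
    untrained_report = evaluate_servo(untrained, test_videos, config)

    m = report.metrics
    return {
        "MAE_1st_um": m.MAE_1st,
        "ACC_dir": m.ACC_dir,
        "MAE_C_um": m.MAE_C_mean,
        "MAE_C_sd_um": m.MAE_C_sd,
        "W_B_um": m.W_B,
        "BM_post": m.BM,
        "convergence_rate": report.convergence_rate,
        "entry_step_385": report.entry_step_385,
        "entry_step_m320": report.entry_step_m320,
        "bm_gain_far_starts": report.bm_gain_far_starts,
        "final_train_loss": fit.epoch_losses[-1],
        "finetuned_W_B_um": fine_report.metrics.W_B,
        "finetuned_convergence_rate": fine_report.convergence_rate,
        "untrained_W_B_um": untrained_report.metrics.W_B,
        "n_runs": m.n_runs,
    }
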