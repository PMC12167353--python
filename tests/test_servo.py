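"""Closed-loop servo: update bookkeeping, convergence rule, metrics."""

import numpy as np
import pytest

from pcleservo.scanner import Frame
from pcleservo.servo import (
    ControllerConfig,
    OracleRegressor,
    ServoRun,
    blur_metric,
    compute_metrics,
    detect_convergence,
    laplacian_variance,
    run_kstep,
    step,
)


@pytest.fixture
def cfg():
    return ControllerConfig()  # L_max=10, N_S=3, K=20, band 35 µm


class ZeroModel:
    """Always predicts 0 µm: the probe must never move."""

    def predict_single(self, frame):
        return 0.0

    def predict_sequence(self, frames):
        return np.zeros(len(frames))


def run_from_positions(P0, positions):
    return ServoRun(P0=P0, positions=list(positions), predictions=[0.0] * (len(positions) - 1))


class TestStepAndBuffer:
    def test_guided_controller_active_exactly_first_ns_steps(self, cfg, clean_video):
        run = run_kstep(clean_video, OracleRegressor(), 385.0, cfg)
        assert run.used_single_frame == [True] * 3 + [False] * 17

    def test_buffer_uses_all_frames_when_fewer_than_l_max(self, cfg, clean_video):
        class WindowProbe(ZeroModel):
            windows = []

            def predict_sequence(self, frames):
                self.windows.append(len(frames))
                return np.zeros(len(frames))

        probe = WindowProbe()
        run_kstep(clean_video, probe, 100.0, cfg)
        # sequential model first called at step 3 with 4 acquired frames
        assert probe.windows[0] == 4
        assert probe.windows[-1] == cfg.L_max

    def test_update_rule_bookkeeping(self, cfg, clean_video):
        run = run_kstep(clean_video, OracleRegressor(), 385.0, cfg)
        for k in range(cfg.K):
            if k not in run.clamp_events:
                np.testing.assert_allclose(
                    run.positions[k + 1] - run.positions[k], -run.predictions[k], atol=1e-9
                )

    def test_positions_clamped_to_sweep_range(self, cfg, clean_video):
        class Runaway(ZeroModel):
            def predict_single(self, frame):
                return -500.0

        run = run_kstep(clean_video, Runaway(), 100.0, cfg)
        assert max(run.positions) <= 400.0
        assert run.clamp_events

    def test_uninitialized_model_rejected(self, cfg, clean_video):
        with pytest.raises(RuntimeError):
            step(ServoRun(P0=0.0), clean_video, None, cfg)


class TestOracleClosedLoop:
    def test_oracle_converges_in_one_move_from_every_grid_start(self, cfg, clean_video):
        for P0 in clean_video.positions()[::10]:
            run = run_kstep(clean_video, OracleRegressor(), float(P0), cfg)
            assert run.converged_at is not None and run.converged_at <= 1
            np.testing.assert_allclose(run.positions[1:], 0.0, atol=1e-9)

    def test_zero_model_never_converges_from_far_start(self, cfg, clean_video):
        run = run_kstep(clean_video, ZeroModel(), 385.0, cfg)
        assert run.converged_at is None
        np.testing.assert_allclose(run.positions, 385.0)

    def test_oracle_metrics_are_perfect(self, cfg, clean_video):
        runs = [
            run_kstep(clean_video, OracleRegressor(), float(P0), cfg)
            for P0 in (385.0, -320.0, 100.0, -55.0)
        ]
        report = compute_metrics(runs, cfg)
        assert report.MAE_1st == 0.0
        assert report.ACC_dir == 1.0
        assert report.W_B == 0.0
        assert report.n_converged == len(runs)


class TestConvergenceRule:
    def test_definition_example(self, cfg):
        run = run_from_positions(385.0, [385, 150, 20, 10, 5] + [5] * 16)
        assert detect_convergence(run, cfg) == 2

    def test_never_inside_band(self, cfg):
        run = run_from_positions(385.0, [385] * 21)
        assert detect_convergence(run, cfg) is None

    def test_retrospective_rule_disqualifies_reentries(self, cfg):
        run = run_from_positions(385.0, [385, 20, 60, 10, 5] + [5] * 16)
        assert detect_convergence(run, cfg) == 3

    def test_late_exit_disqualifies_run(self, cfg):
        run = run_from_positions(385.0, [385, 10, 10, 10] + [10] * 16 + [80])
        assert detect_convergence(run, cfg) is None


class TestMetrics:
    def test_band_width_from_post_convergence_positions(self, cfg):
        run = run_from_positions(100.0, [100, 30, 40, 35] + [35] * 17)
        run.converged_at = 1
        report = compute_metrics([run], cfg)
        assert report.W_B == 10.0

    def test_direction_accuracy_counts_sign_matches(self, cfg):
        a = run_from_positions(100.0, [100] * 21)
        a.predictions = [50.0] + [0.0] * 20
        b = run_from_positions(-100.0, [-100] * 21)
        b.predictions = [50.0] + [0.0] * 20
        report = compute_metrics([a, b], cfg)
        assert report.ACC_dir == 0.5

    def test_degenerate_single_run(self, cfg):
        run = run_from_positions(50.0, [50.0] + [-30.0] * 20)
        run.converged_at = 1
        report = compute_metrics([run], cfg)
        assert report.W_B == 0.0
        assert report.MAE_C_mean == 30.0

    def test_no_converged_runs_reports_infinite_width(self, cfg):
        run = run_from_positions(385.0, [385.0] * 21)
        report = compute_metrics([run], cfg)
        assert report.n_converged == 0
        assert report.W_B == float("inf")

    def test_empty_runs_rejected(self, cfg):
        with pytest.raises(ValueError):
            compute_metrics([], cfg)


class TestBlurMetric:
    def test_optimum_frame_scores_one(self, clean_video):
        assert blur_metric(clean_video.frame_at(0.0), clean_video) == pytest.approx(1.0)

    def test_constant_frame_scores_zero(self, clean_video):
        flat = Frame(pixels=np.full((64, 64), 0.3), position=0.0)
        assert blur_metric(flat, clean_video) == 0.0

    def test_sharper_frame_scores_higher(self, clean_video):
        near = blur_metric(clean_video.frame_at(50.0), clean_video)
        far = blur_metric(clean_video.frame_at(400.0), clean_video)
        assert near > far

    def test_non_finite_frame_rejected(self):
        with pytest.raises(ValueError):
            laplacian_variance(np.full((8, 8), np.inf))
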