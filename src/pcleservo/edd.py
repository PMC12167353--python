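"""Exponential distance discretization (EDD): guided trajectory planning.

From an initial signed probe position P0 the planner emits N positions that
decay exponentially in magnitude toward the optimum, ending at magnitude
alpha, then snaps each to the 5 µm acquisition grid.  Paired with the frames
recorded at those grid positions, the sequence forms a pseudo-labelled
training example of a smooth approach trajectory — no ground-truth distance
labels are needed beyond the recording grid itself.

Decay form (for |P0| > alpha):

    P_i = sign(P0) * |P0| * exp( -(i / (N-1)) * ln(|P0| / alpha) ),  i = 0..N-1

so P_0 = P0 and |P_{N-1}| = alpha, with a constant per-step magnitude ratio
(|P0|/alpha) ** (-1/(N-1)).  The printed source form of this recurrence has
the exponent's sign flipped, which would make the magnitudes grow as
P0**2/alpha instead of converging; the divergent literal form is kept behind
``literal_form=True`` for inspection only.

Discretization (floor mode, the default): floor(P_i / 5) * 5.  Floor sends
positive tails exactly to 0 but negative tails to -5; ``nearest`` mode
(round half away from zero) is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scanner import Frame, SyntheticVideo

__all__ = ["EDDConfig", "Trajectory", "plan_trajectory", "discretize", "trajectory_to_frames"]

POSITION_LIMIT_UM = 400.0


@dataclass
class EDDConfig:
    alpha: float = 0.1          # µm; terminal magnitude of the planned decay
    n_steps: int = 10           # N; equals the training sequence length L
    grid_step: float = 5.0      # µm
    rounding_mode: str = "floor"  # "floor" (literal definition) or "nearest"

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.rounding_mode not in ("floor", "nearest"):
            raise ValueError(f"unknown rounding_mode {self.rounding_mode!r}")


@dataclass
class Trajectory:
    positions: np.ndarray              # continuous planned positions, µm
    discretized_positions: np.ndarray  # grid-snapped positions, µm


def discretize(position: float, config: EDDConfig) -> float:
    """Snap a planned position to the acquisition grid."""
    config.validate()
    if not np.isfinite(position):
        raise ValueError("position must be finite")
    q = position / config.grid_step
    if config.rounding_mode == "floor":
        return float(np.floor(q) * config.grid_step)
    # round half away from zero
    return float(np.sign(q) * np.floor(abs(q) + 0.5) * config.grid_step)


def plan_trajectory(P0: float, config: EDDConfig, literal_form: bool = False) -> Trajectory:
    """Plan the exponential approach trajectory from initial position P0."""
    config.validate()
    if abs(P0) > POSITION_LIMIT_UM:
        raise ValueError(f"|P0| must be <= {POSITION_LIMIT_UM} µm, got {P0}")
    N = config.n_steps
    if P0 == 0:
        positions = np.zeros(N)
    elif abs(P0) <= config.alpha:
        # already at the optimum's resolution limit: hold position
        positions = np.full(N, float(P0))
    else:
        i = np.arange(N)
        rate = np.log(abs(P0) / config.alpha) / (N - 1)
        sign = 1.0 if literal_form else -1.0
        positions = np.sign(P0) * abs(P0) * np.exp(sign * rate * i)
    disc = np.array([discretize(p, config) for p in positions])
    return Trajectory(positions=positions, discretized_positions=disc)


def trajectory_to_frames(traj: Trajectory, video: SyntheticVideo) -> list[Frame]:
    """Look up the recorded frame at every discretized trajectory position."""
    frames = []
    for pos in traj.discretized_positions:
        try:
            frames.append(video.frame_at(float(pos)))
        except KeyError as err:
            raise KeyError(
                f"trajectory position {pos} µm is not on the video grid "
                "(discretization bug or out-of-range plan)"
            ) from err
    return frames
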