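"""Synthetic pCLE scanner: a virtual probe/tissue environment.

Emulates the acquisition geometry of a stepper-driven confocal miniprobe
sweep: one video is one tissue sample imaged at every 5 µm probe position
between -400 and +400 µm around the optimal (least blur) scanning position.
Positions are signed distances relative to that optimum, which the simulator
places at 0 by construction.

Image formation per frame:

    pixels = clip( blur(texture, sigma(|d|)) * (1 + speckle)
                   + tilt(d) + gaussian_noise, 0, 1 )

with a defocus law sigma(|d|) = sigma0 + c * |d|**gamma, gamma > 1 so the
blur gradient flattens near the optimum (image-clarity improvements become
less apparent close to the best position, as observed on real pCLE).

``tilt(d)`` is a signed illumination-gradient cue with amplitude
proportional to the signed position: on real tissue the two sides of the
optimal plane are visually distinct (the probe compresses tissue on one
side), which is what makes the sign of the distance learnable from a single
frame.  Pure defocus is an even function of d, so a simulator without such a
cue would make the regression target unidentifiable.  Set
``asymmetry_strength = 0`` for a strictly symmetric scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import fourier_gaussian, gaussian_filter

__all__ = [
    "ScannerConfig",
    "Frame",
    "SyntheticVideo",
    "generate_texture",
    "render_frame",
    "generate_video",
    "generate_dataset",
    "sigma_at",
]

_GRID_TOL = 1e-6


@dataclass
class ScannerConfig:
    """Geometry, optics and noise of the virtual scanner."""

    image_size: int = 64
    grid_min: float = -400.0
    grid_max: float = 400.0
    grid_step: float = 5.0
    blur_base: float = 0.5          # sigma0, px
    blur_gain: float = 7.5 / 8000.0  # c, px/µm**gamma; sigma(400) = 8 px
    blur_exponent: float = 1.5      # gamma > 1: flattened gradient near 0
    speckle_strength: float = 0.08
    gaussian_noise_sd: float = 0.02
    asymmetry_strength: float = 0.3  # signed illumination tilt amplitude
    texture_blob_count: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not (self.grid_min < 0 < self.grid_max):
            raise ValueError("grid must satisfy grid_min < 0 < grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        span = self.grid_max - self.grid_min
        if abs(span / self.grid_step - round(span / self.grid_step)) > _GRID_TOL:
            raise ValueError("(grid_max - grid_min) must be divisible by grid_step")
        if self.blur_base < 0 or self.blur_gain <= 0:
            raise ValueError("blur_base must be >= 0 and blur_gain > 0")
        if self.blur_exponent <= 1:
            raise ValueError("blur_exponent must be > 1 (flattened gradient near optimum)")
        if self.speckle_strength < 0 or self.gaussian_noise_sd < 0 or self.asymmetry_strength < 0:
            raise ValueError("noise strengths must be nonnegative")
        if self.texture_blob_count < 1:
            raise ValueError("texture_blob_count must be positive")

    def grid_positions(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Frame:
    """One grayscale frame with its signed probe position (µm)."""

    pixels: np.ndarray
    position: float

    def validate(self, config: ScannerConfig | None = None) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite pixels")
        if self.pixels.min() < -_GRID_TOL or self.pixels.max() > 1 + _GRID_TOL:
            raise ValueError("frame pixels must lie in [0, 1]")
        if config is not None:
            if not (config.grid_min - _GRID_TOL <= self.position <= config.grid_max + _GRID_TOL):
                raise ValueError("frame position outside the acquisition grid range")
            q = self.position / config.grid_step
            if abs(q - round(q)) > _GRID_TOL:
                raise ValueError("frame position is not a multiple of grid_step")


@dataclass
class SyntheticVideo:
    """One simulated probe sweep: a frame at every grid position."""

    frames: list[Frame]
    texture_seed: int
    optimal_position: float = 0.0
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.frames])

    def frame_at(self, position: float) -> Frame:
        """Exact-position lookup; off-grid positions are an error."""
        step = self.frames[1].position - self.frames[0].position
        if not self._index:
            self._index = {int(round(f.position / step * 1000)): i for i, f in enumerate(self.frames)}
        key = position / step
        if abs(key - round(key)) > _GRID_TOL:
            raise KeyError(f"position {position} µm is not on the acquisition grid")
        idx = self._index.get(int(round(key * 1000)))
        if idx is None:
            raise KeyError(f"position {position} µm is outside the recorded sweep")
        return self.frames[idx]


def sigma_at(config: ScannerConfig, position: float) -> float:
    """Defocus blur sigma (px) at a signed position (µm); even in position."""
    return config.blur_base + config.blur_gain * abs(position) ** config.blur_exponent


def generate_texture(config: ScannerConfig, texture_seed: int) -> np.ndarray:
    """Random multi-scale tissue texture in [0, 1].

    A dense field of soft Gaussian blobs with log-uniform radii down to
    ~1 px — emulating the many small stained nuclei of cellular tissue —
    plus fine micro-granularity, so the texture carries high-frequency
    energy at multiple scales that defocus blur measurably removes.
    """
    config.validate()
    s = config.image_size
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, texture_seed & 0x7FFFFFFF])
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    img = np.zeros((s, s))
    n = config.texture_blob_count
    cx = rng.uniform(0, s, n)
    cy = rng.uniform(0, s, n)
    radii = np.exp(rng.uniform(np.log(1.0), np.log(s / 8.0), n))
    amps = rng.uniform(-1.0, 1.0, n)
    for i in range(n):
        img += amps[i] * np.exp(-((xx - cx[i]) ** 2 + (yy - cy[i]) ** 2) / (2 * radii[i] ** 2))
    span = img.max() - img.min()
    if span < 1e-12:  # pathological draw; keep the contract pixels in [0,1]
        return np.full((s, s), 0.5)
    # cellular micro-granularity: broadband fine-scale structure that defocus
    # blur removes (blobs alone are too smooth to carry band-limited energy
    # near Nyquist)
    grain = gaussian_filter(rng.standard_normal((s, s)), 0.7)
    img = img + 0.25 * span * grain / max(grain.std(), 1e-12)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


def render_frame(
    texture: np.ndarray,
    position: float,
    config: ScannerConfig,
    noise_seed: int = 0,
) -> Frame:
    """Render the frame seen by the probe at a signed position."""
    config.validate()
    if abs(position) > config.grid_max + _GRID_TOL:
        raise ValueError(f"position {position} µm outside the ±{config.grid_max} µm range")
    sigma = sigma_at(config, position)
    if sigma > 0:
        # exact Gaussian transfer function (periodic boundary): a truncated
        # spatial kernel would leave a sidelobe floor in the spectrum that
        # breaks the monotone blur-frequency relationship at heavy defocus
        img = np.fft.ifft2(fourier_gaussian(np.fft.fft2(texture), sigma)).real
    else:
        img = texture.copy()
    if config.asymmetry_strength > 0 and position != 0:
        s = config.image_size
        ramp = (np.arange(s) / (s - 1)) - 0.5
        img = img + config.asymmetry_strength * (position / config.grid_max) * ramp[None, :]
    if config.speckle_strength > 0 or config.gaussian_noise_sd > 0:
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, noise_seed & 0x7FFFFFFF])
        if config.speckle_strength > 0:
            img = img * (1.0 + config.speckle_strength * rng.standard_normal(img.shape))
        if config.gaussian_noise_sd > 0:
            img = img + config.gaussian_noise_sd * rng.standard_normal(img.shape)
    return Frame(pixels=np.clip(img, 0.0, 1.0), position=float(position))


def generate_video(config: ScannerConfig, texture_seed: int) -> SyntheticVideo:
    """One full sweep: a frame at every grid position, sorted by position."""
    config.validate()
    texture = generate_texture(config, texture_seed)
    frames = []
    for i, pos in enumerate(config.grid_positions()):
        noise_seed = (texture_seed * 100_003 + i) & 0x7FFFFFFF
        frames.append(render_frame(texture, float(pos), config, noise_seed=noise_seed))
    return SyntheticVideo(frames=frames, texture_seed=texture_seed)


def generate_dataset(
    config: ScannerConfig,
    n_train_videos: int,
    n_test_videos: int,
    seed: int,
) -> tuple[list[SyntheticVideo], list[SyntheticVideo]]:
    """Train/test sweeps with disjoint texture seeds, reproducible per seed."""
    config.validate()
    if n_train_videos < 1 or n_test_videos < 1:
        raise ValueError("n_train_videos and n_test_videos must be >= 1")
    base = (seed & 0x3FFFFFFF) * 1000
    train = [generate_video(config, base + i) for i in range(n_train_videos)]
    test = [generate_video(config, base + n_train_videos + i) for i in range(n_test_videos)]
    return train, test
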