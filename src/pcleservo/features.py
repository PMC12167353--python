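"""Spatial and frequency domain features, fused per frame.

Each frame is summarized by a fixed-length vector with two provenances:

* a **spatial** branch: a small trainable strided convolutional encoder with
  global average pooling — a lightweight stand-in for a pretrained
  perceptual feature extractor, kept trainable (and freezable for the
  fine-tuning regime);
* a **frequency** branch: log energies of concentric radial bands of the 2-D
  Fourier magnitude spectrum.  Defocus blur attenuates high spatial
  frequencies, so the band profile carries the probe-distance signal
  directly.

The two are concatenated and passed through the fusion encoder ε (one
trainable affine map with a GELU nonlinearity) to the fused dimension F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .scanner import Frame

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureSequence",
    "FeatureExtractor",
    "extract_spatial",
    "extract_frequency",
    "fuse",
    "featurize_sequence",
    "normalize_pixels",
    "global_stats",
    "window_relative",
    "fusion_extra",
    "band_fractions",
]


@dataclass
class FeatureConfig:
    spatial_dim: int = 32
    n_bands: int = 8
    fused_dim: int = 32   # F, the length of a fused FeatureVector
    seed: int = 0


@dataclass
class FeatureVector:
    values: np.ndarray
    source_position: float | None = None


@dataclass
class FeatureSequence:
    """Ordered fused feature vectors, aligned with their frame positions."""

    vectors: np.ndarray  # [L, F]
    positions: list[float | None]

    def __len__(self) -> int:
        return self.vectors.shape[0]


STATS_DIM = 4


def global_stats(pixels: np.ndarray) -> np.ndarray:
    """Global raw-frame statistics [mean, log sd, x moment, y moment].

    Companion to :func:`normalize_pixels`: standardization removes exposure
    and contrast per frame; these four numbers retain the global intensity
    level, contrast, and the two first spatial intensity moments (signed
    illumination-gradient strength).  They are consumed as within-window
    differences (:func:`window_relative`), where per-sample texture biases
    cancel.  Fixed affines put each on a ~unit scale.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    s = pixels.shape[-1]
    ramp = np.arange(s) / (s - 1) - 0.5
    return np.array(
        [
            (pixels.mean() - 0.5) * 10.0,
            np.log(max(pixels.std(), 1e-8)) + 2.5,
            (pixels * ramp[None, :]).mean() * 100.0,
            (pixels * ramp[:, None]).mean() * 100.0,
        ]
    )


def window_relative(freq: np.ndarray, stats: np.ndarray) -> np.ndarray:
    """Window-relative features: differences against the sharpest frame.

    freq: [..., L, n_bands]; stats: [..., L, 4].  The reference frame of a
    window is the one with the highest contrast (max log-sd channel — the
    sharpest frame in the acquisition buffer).  Every band energy and every
    global statistic is reported as (value - value_at_reference).  Absolute
    spectra and moments are confounded by the tissue sample's own texture;
    differences within one video cancel that confound exactly, which is what
    lets a model trained on a handful of samples stay calibrated on a new
    one.  A window of one frame maps to zeros.

    Returns [..., L, n_bands + 4].
    """
    freq = np.asarray(freq, dtype=np.float64)
    stats = np.asarray(stats, dtype=np.float64)
    ref = np.argmax(stats[..., 1], axis=-1)  # sharpest frame index per window
    joint = np.concatenate([freq, stats], axis=-1)
    ref_vals = np.take_along_axis(joint, ref[..., None, None], axis=-2)
    return joint - ref_vals


def fusion_extra(freq: np.ndarray, stats: np.ndarray) -> np.ndarray:
    """Auxiliary fusion inputs [..., L, n_bands + 6].

    Concatenation of the window-relative differences (n_bands + 4, see
    :func:`window_relative`) and the absolute spatial intensity moments
    (2).  The moments are the one texture-invariant absolute cue — the
    signed illumination gradient scales with the signed distance regardless
    of the tissue sample — so they are passed through untouched.
    """
    rel = window_relative(freq, stats)
    return np.concatenate([rel, np.asarray(stats, float)[..., 2:4]], axis=-1)


def normalize_pixels(pixels: np.ndarray) -> np.ndarray:
    """Per-frame standardization, remapped to a fixed display range.

    z-scores the frame, then applies the affine remap 0.5 + z/6 clipped to
    [0, 1].  Removes per-frame brightness/contrast so features respond to
    structure, not exposure; spatial patterns (texture, gradients) survive.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("frame contains non-finite pixels")
    sd = pixels.std()
    if sd < 1e-12:
        return np.full_like(pixels, 0.5)
    z = (pixels - pixels.mean()) / sd
    # no clipping: a hard clip would inject spurious high-frequency energy
    return 0.5 + z / 6.0


class SpatialEncoder(nn.Module):
    """Strided conv stack -> global (mean + first-moment) pooling -> projection.

    Pooling keeps, per channel, the global average and the two first spatial
    moments (x- and y-weighted averages).  Plain average pooling is
    translation invariant and therefore blind to global intensity gradients;
    the moment channels expose them directly, which matters because the
    direction of approach to the focal plane shows up as a signed
    illumination gradient.  A LayerNorm keeps the output on a unit scale
    regardless of how small the conv responses are.
    """

    def __init__(self, spatial_dim: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(1, 8, kernel=5, stride=4, pad=2, rng=rng)
        self.conv2 = nn.Conv2d(8, 16, kernel=3, stride=2, pad=1, rng=rng)
        self.proj = nn.Linear(48, spatial_dim, rng=rng)
        self.norm = nn.LayerNorm(spatial_dim)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """x: [B, 1, S, S] normalized frames -> [B, spatial_dim]."""
        h = nn.relu(self.conv1(x))
        h = nn.relu(self.conv2(h))
        s = h.shape[-1]
        ramp = nn.Tensor(np.arange(s) / (s - 1) - 0.5)
        mean = h.mean(axis=-1).mean(axis=-1)                 # [B, C]
        mx = (h * ramp).mean(axis=-1).mean(axis=-1)          # x moment
        my = (h * nn.reshape(ramp, (s, 1))).mean(axis=-1).mean(axis=-1)
        pooled = nn.concat([mean, mx, my], axis=-1)          # [B, 3C]
        return self.norm(self.proj(pooled))


def _radial_band_masks(size: int, n_bands: int) -> np.ndarray:
    """Boolean masks [n_bands, S, S] of concentric rings in fft2 layout.

    Radius is normalized by the axis Nyquist frequency (0.5 cycles/px); the
    outermost ring absorbs the corner bins beyond it.
    """
    f = np.fft.fftfreq(size)
    r = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2) / 0.5
    edges = np.linspace(0.0, 1.0, n_bands + 1)
    masks = [(r >= lo) & (r < hi) for lo, hi in zip(edges[:-1], edges[1:-1])]
    masks.append(r >= edges[-2])
    return np.stack(masks)


_MASK_CACHE: dict[tuple[int, int], np.ndarray] = {}


def band_fractions(
    pixels: np.ndarray,
    n_bands: int = 8,
    noise_floor_correction: bool = True,
) -> np.ndarray:
    """Radial band energy fractions of the power spectrum, summing to 1.

    With ``noise_floor_correction`` the median power of the outermost band is
    subtracted from every non-DC bin (clipped at zero) before integrating the
    bands.  pCLE-like frames carry a white sensor-noise floor that otherwise
    dominates the high-frequency bands of heavily defocused frames and
    destroys the monotone blur-to-spectrum relationship the regression relies
    on; on noise-free frames the correction is a small, ordering-preserving
    perturbation.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    pixels = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("frame contains non-finite pixels")
    key = (pixels.shape[0], n_bands)
    if key not in _MASK_CACHE:
        _MASK_CACHE[key] = _radial_band_masks(pixels.shape[0], n_bands)
    masks = _MASK_CACHE[key]
    power = np.abs(np.fft.fft2(pixels)) ** 2
    if noise_floor_correction:
        floor = np.median(power[masks[-1]])
        dc = power[0, 0]
        power = np.maximum(power - floor, 0.0)
        power[0, 0] = dc
    energies = np.array([power[m].sum() for m in masks])
    total = energies.sum()
    if total <= 0:
        return np.eye(n_bands)[0]
    return energies / total


# Fixed affine placing typical log band fractions on a ~unit scale.
_FREQ_SHIFT, _FREQ_SCALE = 7.0, 3.0


def extract_frequency(frame: Frame | np.ndarray, n_bands: int = 8) -> np.ndarray:
    """Per-band log energy fractions on a fixed affine scale.

    The affine (log f + 7) / 3 centers the typical dynamic range of log
    fractions so the frequency branch enters the fusion encoder on the same
    scale as the normalized spatial branch.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    fractions = band_fractions(pixels, n_bands)
    return (np.log(fractions + 1e-12) + _FREQ_SHIFT) / _FREQ_SCALE


class FeatureExtractor(nn.Module):
    """Spatial encoder + radial frequency bands + fusion encoder ε."""

    def __init__(self, config: FeatureConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.spatial = SpatialEncoder(config.spatial_dim, rng)
        # ε fuses spatial features, absolute frequency bands, the
        # window-relative band + statistic differences, and the absolute
        # intensity moments
        self.extra_dim = config.n_bands + STATS_DIM + 2
        self.eps = nn.Linear(
            config.spatial_dim + config.n_bands + self.extra_dim, config.fused_dim, rng=rng
        )
        self.use_nonlinearity = True

    # -- trainable batched path -------------------------------------------
    def forward_batch(
        self,
        pixels: np.ndarray,
        freq: np.ndarray,
        extra: np.ndarray | None = None,
    ) -> nn.Tensor:
        """pixels: [B, S, S] normalized frames; freq: [B, n_bands];
        extra: [B, n_bands + 6] :func:`fusion_extra` features -> [B, F]."""
        x = nn.Tensor(pixels[:, None, :, :])
        spatial = self.spatial(x)
        if extra is None:
            extra = np.zeros((pixels.shape[0], self.extra_dim))
        fused_in = nn.concat([spatial, nn.Tensor(freq), nn.Tensor(extra)], axis=-1)
        out = self.eps(fused_in)
        return nn.gelu(out) if self.use_nonlinearity else out

    def fuse_batch(
        self,
        spatial: np.ndarray,
        freq: np.ndarray,
        extra: np.ndarray,
    ) -> nn.Tensor:
        """Fusion ε over precomputed spatial features (inference fast path)."""
        fused_in = nn.Tensor(np.concatenate([spatial, freq, extra], axis=-1))
        out = self.eps(fused_in)
        return nn.gelu(out) if self.use_nonlinearity else out

    # -- per-frame numpy convenience paths --------------------------------
    def frame_inputs(self, frame: Frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cacheable per-frame inputs: (spatial features, bands, raw stats).

        The expensive conv pass happens here once per frame; window-relative
        fusion is cheap and re-done as the acquisition buffer grows.
        """
        pixels = normalize_pixels(frame.pixels)
        freq = extract_frequency(pixels, self.config.n_bands)
        spatial = self.spatial(nn.Tensor(pixels[None, None])).data[0]
        return spatial, freq, global_stats(frame.pixels)

    def frame_features(self, frame: Frame) -> np.ndarray:
        """Fused features of an isolated frame (window of one: zero rel)."""
        spatial, freq, stats = self.frame_inputs(frame)
        extra = fusion_extra(freq[None], stats[None])
        return self.fuse_batch(spatial[None], freq[None], extra).data[0]

    def window_features(
        self, inputs: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> np.ndarray:
        """Fused features [L, F] of an acquisition window from cached inputs."""
        spatial = np.stack([i[0] for i in inputs])
        freq = np.stack([i[1] for i in inputs])
        extra = fusion_extra(freq, np.stack([i[2] for i in inputs]))
        return self.fuse_batch(spatial, freq, extra).data

    def spatial_parameters(self) -> list[nn.Tensor]:
        return self.spatial.parameters()


def extract_spatial(frame: Frame, encoder: SpatialEncoder) -> np.ndarray:
    """Spatial branch features of one (already acquired) frame."""
    if not np.all(np.isfinite(frame.pixels)):
        raise ValueError("frame contains non-finite pixels")
    pixels = normalize_pixels(frame.pixels)
    return encoder(nn.Tensor(pixels[None, None])).data[0]


def fuse(
    spatial: np.ndarray,
    frequency: np.ndarray,
    extractor: FeatureExtractor,
    rel_stats: np.ndarray | None = None,
) -> FeatureVector:
    """Fusion encoder ε: concat -> affine -> (optional) GELU."""
    if rel_stats is None:
        rel_stats = np.zeros(extractor.extra_dim)
    vec = np.concatenate(
        [np.asarray(spatial, float), np.asarray(frequency, float), np.asarray(rel_stats, float)]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature inputs")
    if vec.shape[0] != extractor.eps.w.data.shape[0]:
        raise ValueError(
            f"fusion expects length {extractor.eps.w.data.shape[0]}, got {vec.shape[0]}"
        )
    out = nn.add(nn.matmul(nn.Tensor(vec[None]), extractor.eps.w), extractor.eps.b)
    if extractor.use_nonlinearity:
        out = nn.gelu(out)
    return FeatureVector(values=out.data[0])


def featurize_sequence(frames: list[Frame], extractor: FeatureExtractor) -> FeatureSequence:
    """Order-preserving extract+fuse over a frame sequence."""
    if len(frames) == 0:
        raise ValueError("cannot featurize an empty frame sequence")
    pixels = np.stack([normalize_pixels(f.pixels) for f in frames])
    freq = np.stack([extract_frequency(p, extractor.config.n_bands) for p in pixels])
    extra = fusion_extra(freq, np.stack([global_stats(f.pixels) for f in frames]))
    vectors = extractor.forward_batch(pixels, freq, extra).data
    return FeatureSequence(vectors=vectors, positions=[f.position for f in frames])
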