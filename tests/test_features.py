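"""Spatial/frequency features and the fusion encoder."""

import numpy as np
import pytest

from pcleservo import nn
from pcleservo.features import (
    FeatureConfig,
    FeatureExtractor,
    band_fractions,
    extract_frequency,
    extract_spatial,
    featurize_sequence,
    fuse,
    fusion_extra,
    global_stats,
    normalize_pixels,
    window_relative,
)
from pcleservo.scanner import Frame, ScannerConfig, generate_texture, render_frame


@pytest.fixture(scope="module")
def extractor():
    return FeatureExtractor(FeatureConfig(seed=0))


class TestFrequency:
    def test_constant_frame_is_pure_dc(self):
        frac = band_fractions(np.full((32, 32), 0.5), 8)
        np.testing.assert_allclose(frac[0], 1.0)
        np.testing.assert_allclose(frac[1:], 0.0, atol=1e-15)

    def test_mirror_symmetry(self, texture):
        a = extract_frequency(texture, 8)
        b = extract_frequency(texture[:, ::-1], 8)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_sharp_frame_has_larger_top_band_fraction(self, clean_config, texture):
        sharp = render_frame(texture, 0.0, clean_config).pixels
        blurred = render_frame(texture, 300.0, clean_config).pixels
        assert band_fractions(sharp, 8)[-1] > band_fractions(blurred, 8)[-1]

    def test_rejects_too_few_bands(self, texture):
        with pytest.raises(ValueError):
            extract_frequency(texture, 1)

    def test_rejects_non_finite(self):
        bad = np.full((16, 16), np.nan)
        with pytest.raises(ValueError):
            extract_frequency(bad, 4)


class TestSpatial:
    def test_zero_final_layer_gives_zero_vector(self, extractor):
        enc = FeatureExtractor(FeatureConfig(seed=1)).spatial
        enc.proj.w.data[:] = 0.0
        enc.proj.b.data[:] = 0.0
        frame = Frame(pixels=np.full((64, 64), 0.5), position=0.0)
        np.testing.assert_allclose(extract_spatial(frame, enc), 0.0, atol=1e-12)

    def test_deterministic(self, extractor, noisy_video):
        frame = noisy_video.frames[10]
        a = extract_spatial(frame, extractor.spatial)
        b = extract_spatial(frame, extractor.spatial)
        np.testing.assert_array_equal(a, b)

    def test_blur_changes_spatial_features(self, extractor, clean_config, texture):
        sharp = render_frame(texture, 0.0, clean_config)
        blurred = render_frame(texture, 350.0, clean_config)
        a = extract_spatial(sharp, extractor.spatial)
        b = extract_spatial(blurred, extractor.spatial)
        assert np.linalg.norm(a - b) > 0


class TestFusion:
    def test_zero_inputs_zero_map_give_zero_vector(self):
        ex = FeatureExtractor(FeatureConfig(seed=2))
        ex.eps.w.data[:] = 0.0
        ex.eps.b.data[:] = 0.0
        out = fuse(np.zeros(32), np.zeros(8), ex)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_identity_map_reproduces_concatenation(self):
        cfg = FeatureConfig(spatial_dim=4, n_bands=2, fused_dim=4 + 2 + (2 + 4 + 2), seed=0)
        ex = FeatureExtractor(cfg)
        ex.eps.w.data[:] = np.eye(cfg.fused_dim)
        ex.eps.b.data[:] = 0.0
        ex.use_nonlinearity = False
        spatial, freq = np.arange(4.0), np.array([1.0, -1.0])
        out = fuse(spatial, freq, ex)
        np.testing.assert_allclose(out.values[:6], np.concatenate([spatial, freq]))

    def test_distinct_frames_fuse_to_distinct_vectors(self, extractor, noisy_video):
        a = extractor.frame_features(noisy_video.frames[0])
        b = extractor.frame_features(noisy_video.frames[80])
        assert np.linalg.norm(a - b) > 0

    def test_shape_mismatch_rejected(self, extractor):
        with pytest.raises(ValueError):
            fuse(np.zeros(5), np.zeros(8), extractor)


class TestWindowRelative:
    def test_single_frame_window_maps_to_zero_differences(self):
        freq = np.random.default_rng(0).standard_normal((1, 8))
        stats = np.array([[0.1, -0.5, 0.3, 0.2]])
        rel = window_relative(freq, stats)
        np.testing.assert_allclose(rel, 0.0, atol=1e-15)

    def test_reference_is_sharpest_frame(self):
        freq = np.zeros((3, 2))
        stats = np.array([[0.0, -1.0, 5.0, 0.0], [0.0, 0.5, 7.0, 0.0], [0.0, -2.0, 1.0, 0.0]])
        rel = window_relative(freq, stats)
        # frame 1 has max log-sd -> its moments become the reference
        np.testing.assert_allclose(rel[:, 2 + 2], [-2.0, 0.0, -6.0])

    def test_per_video_constant_offsets_cancel(self):
        rng = np.random.default_rng(1)
        freq = rng.standard_normal((5, 8))
        stats = rng.standard_normal((5, 4))
        off_f, off_s = rng.standard_normal(8), rng.standard_normal(4)
        a = window_relative(freq, stats)
        b = window_relative(freq + off_f, stats + off_s)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSequence:
    def test_singleton_sequence(self, extractor, noisy_video):
        seq = featurize_sequence([noisy_video.frames[0]], extractor)
        assert len(seq) == 1

    def test_order_and_shape_preserved(self, extractor, noisy_video):
        frames = noisy_video.frames[0:100:10]
        seq = featurize_sequence(frames, extractor)
        assert seq.vectors.shape == (10, extractor.config.fused_dim)
        assert seq.positions == [f.position for f in frames]

    def test_empty_input_rejected(self, extractor):
        with pytest.raises(ValueError):
            featurize_sequence([], extractor)


def test_normalization_is_affine_without_clipping():
    rng = np.random.default_rng(0)
    pixels = rng.random((32, 32))
    z = normalize_pixels(pixels)
    ref = (pixels - pixels.mean()) / pixels.std()
    np.testing.assert_allclose(z, 0.5 + ref / 6.0, atol=1e-12)


def test_noisy_sharp_frame_separable_after_floor_correction(default_config):
    """The white-noise floor must not mask the blur-frequency relationship:
    an in-focus frame keeps a clearly larger mid-band fraction than heavily
    defocused frames even under speckle and sensor noise."""
    texture = generate_texture(default_config, 21)
    fr = []
    for i, p in enumerate((0.0, 200.0, 400.0)):
        frame = render_frame(texture, p, default_config, noise_seed=i)
        fr.append(band_fractions(normalize_pixels(frame.pixels), 8)[3])
    assert fr[0] > 3 * fr[1] and fr[0] > 3 * fr[2]
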