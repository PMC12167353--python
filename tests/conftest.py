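import numpy as np
import pytest

from pcleservo.scanner import ScannerConfig, generate_texture, generate_video, render_frame


@pytest.fixture(scope="session")
def default_config() -> ScannerConfig:
    return ScannerConfig(seed=0)


@pytest.fixture(scope="session")
def clean_config() -> ScannerConfig:
    """Noise-free, symmetric scanner (asymmetry cue disabled)."""
    return ScannerConfig(
        seed=0, speckle_strength=0.0, gaussian_noise_sd=0.0, asymmetry_strength=0.0
    )


@pytest.fixture(scope="session")
def texture(clean_config):
    return generate_texture(clean_config, texture_seed=7)


@pytest.fixture(scope="session")
def clean_video(clean_config):
    return generate_video(clean_config, texture_seed=3)


@pytest.fixture(scope="session")
def noisy_video(default_config):
    return generate_video(default_config, texture_seed=5)
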