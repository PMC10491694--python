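import numpy as np
import pytest

from trandaug import SynthSpec, default_bank, generate_samples, render_frame


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_frame():
    """A 32x32 asymmetric textured RGB frame (class-0 signature + gradient)."""
    spec = SynthSpec(frame_size=(32, 32), noise_sd=0.0)
    frame = render_frame(spec, 0).astype(np.int64)
    grad = np.linspace(0, 60, 32, dtype=np.int64)
    frame = frame + grad[None, :, None] + grad[:, None, None] // 2
    return np.clip(frame, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def textured_video(textured_frame):
    """20 identical textured frames (constant-content video)."""
    return np.stack([textured_frame] * 20, axis=0)


@pytest.fixture(scope="session")
def const_video():
    """Flat mid-gray 20-frame video."""
    return np.full((20, 24, 24, 3), 128, dtype=np.uint8)


@pytest.fixture(scope="session")
def tiny_synth_samples():
    """Small fast synthetic dataset for augmentation round trips."""
    spec = SynthSpec(
        n_videos=4, n_classes=3, frames_per_video=12, min_segment_len=3,
        frame_size=(24, 24), noise_sd=0.02, seed=11,
    )
    return spec, generate_samples(spec)


@pytest.fixture(scope="session")
def default_synth():
    """The default desk-scale synthetic dataset split 6/2/2."""
    spec = SynthSpec()
    samples = generate_samples(spec)
    return spec, samples[:6], samples[6:8], samples[8:]
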