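import numpy as np
import pytest

import beatflow as bf


@pytest.fixture(scope="session")
def video15():
    """Shared noiseless 1.5 Hz single-center recording (128x128, 30 fps, 10 s)."""
    spec = bf.SceneSpec(beat_frequency=1.5, duration=10.0, texture_seed=7)
    return bf.generate_video(spec)


@pytest.fixture(scope="session")
def flow15(video15):
    """Fine displacement fields of the shared recording vs its rest frame."""
    motion = bf.frame_motion(video15.sequence)
    fields = bf.compute_flow(video15.sequence, motion.t_star)
    return motion, fields


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def shifted_pair(seed, shape=(256, 256), shift=(3, -2), granularity=3.0, pad=20):
    """A textured image pair whose true displacement is a uniform integer
    shift, built by cropping one larger texture twice (no wrap-around)."""
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    H, W = shape
    big = gaussian_filter(rng.standard_normal((H + 2 * pad, W + 2 * pad)), granularity)
    big = (big - big.min()) / (big.max() - big.min())
    ref = big[pad : pad + H, pad : pad + W]
    sr, sc = shift
    mov = big[pad - sr : pad - sr + H, pad - sc : pad - sc + W]
    return ref, mov
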