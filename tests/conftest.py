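import math

import numpy as np
import pytest

from asterflux.core import ImageStack, Trajectory
from asterflux.synthio import SceneParams, bandlimited_texture, warp_backward


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def static_trajectory(x, y, n_frames, interval, pid=0):
    t = np.arange(n_frames) * interval
    return Trajectory(pid, np.arange(n_frames), t,
                      np.full(n_frames, float(x)), np.full(n_frames, float(y)))


@pytest.fixture
def shifted_pair_stack():
    """Two-frame textured stack rigidly shifted by (+3, -2) px, no noise."""
    rng = np.random.default_rng(7)
    tex = bandlimited_texture(rng, (192, 192), 1000.0, 0.2)
    u = np.full(tex.shape, 3.0)
    v = np.full(tex.shape, -2.0)
    fill = bandlimited_texture(rng, tex.shape, 1000.0, 0.2)
    f2 = warp_backward(tex, u, v, fill=fill)
    data = np.stack([tex, f2])[:, None]
    return ImageStack(data, pixel_size=0.65, frame_interval=10.0,
                      channel_names=["tex"])


@pytest.fixture
def uniform_stack():
    data = np.full((4, 1, 64, 64), 5.0)
    return ImageStack(data, 1.0, 10.0, ["u"])


def make_params(**kw):
    defaults = dict(image_shape=(96, 96), pixel_size=0.65,
                    frame_interval=10.0, n_frames=4, bleach_tau=math.inf,
                    flatfield_strength=0.0, noise_sd=0.0,
                    background_offset=0.0, texture_turnover_tau=math.inf,
                    seed=0)
    defaults.update(kw)
    return SceneParams(**defaults)
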