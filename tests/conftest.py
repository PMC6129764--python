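import numpy as np
import pytest

from rsfmripost.io import BrainMask, Volume4D
from rsfmripost.synthetic import (
    PhantomSpec,
    blob_mask,
    full_mask,
    generate_phantom,
    sinusoid,
    white_noise,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A 4x4x4x10 random volume on a 3 mm grid."""
    data = rng.normal(100.0, 5.0, size=(4, 4, 4, 10))
    return Volume4D(data, np.diag([3.0, 3.0, 3.0, 1.0]), tr=2.0)


@pytest.fixture
def small_mask(rng):
    mask = rng.random((4, 4, 4)) > 0.4
    mask[0, 0, 0] = True  # never empty
    return BrainMask(mask, np.diag([3.0, 3.0, 3.0, 1.0]))


@pytest.fixture
def band_limited_phantom():
    """Whole-grid 0.05 Hz sinusoid + small white noise, TR 2 s."""
    spec = PhantomSpec(
        dims=(6, 6, 6), n_frames=120, tr=2.0,
        components=[("global", sinusoid(0.05, 2.0)),
                    ("global", white_noise(0.2))],
        seed=11,
    )
    return generate_phantom(spec), full_mask((6, 6, 6))


def make_blob_phantom(dims, blobs, n_frames=120, noise_sd=0.5, seed=0,
                      amplitude=5.0, freqs=None):
    """Phantom with one shared sinusoid per blob, independent noise overall."""
    freqs = freqs or [0.05 + 0.01 * k for k in range(len(blobs))]
    comps = [(b, sinusoid(f, amplitude)) for b, f in zip(blobs, freqs)]
    comps.append(("global", white_noise(noise_sd)))
    spec = PhantomSpec(dims=dims, n_frames=n_frames, tr=2.0,
                       components=comps, seed=seed)
    return generate_phantom(spec), full_mask(dims)


@pytest.fixture
def one_blob_phantom():
    """A contiguous 10-voxel blob sharing one signal; the rest is noise."""
    dims = (6, 6, 6)
    blob = blob_mask(dims, (1, 1, 1), (2, 5, 1))
    vol, mask = make_blob_phantom(dims, [blob], seed=7)
    return vol, mask, blob


@pytest.fixture
def two_blob_phantom():
    """Two disconnected blobs (5 and 4 voxels) sharing the same signal."""
    dims = (8, 8, 8)
    blob_a = blob_mask(dims, (0, 0, 0), (5, 1, 1))
    blob_b = blob_mask(dims, (0, 4, 4), (4, 1, 1))
    shared = blob_a | blob_b
    vol, mask = make_blob_phantom(dims, [shared], seed=9)
    return vol, mask, blob_a, blob_b
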