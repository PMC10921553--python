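import numpy as np
import pytest

from cbctomics.volumes import MaskVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume(
        data=rng.normal(30.0, 10.0, size=(12, 10, 8)),
        spacing=(1.0, 1.0, 5.0),
        origin=(0.0, 0.0, 0.0),
    )


def make_ball_mask(shape, center, radius_vox, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return MaskVolume(data=(r2 <= radius_vox**2).astype(np.uint8), spacing=spacing)


def random_mask(rng, shape=(12, 12, 12), p=0.2, spacing=(1.0, 1.0, 1.0), nonempty=True):
    data = (rng.random(shape) < p).astype(np.uint8)
    if nonempty and data.sum() == 0:
        data[tuple(s // 2 for s in shape)] = 1
    return MaskVolume(data=data, spacing=spacing)
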