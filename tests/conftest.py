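"""Shared fixtures: tiny images, datasets and models, all seeded."""

import numpy as np
import pytest

import granulonet as gn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gray_image(rng):
    """A 64x64 single-channel image with non-trivial structure."""
    base = rng.random((64, 64, 1)).astype(np.float32)
    base[16:48, 16:48] *= 0.4
    return gn.ImageSample(pixels=base, label=0, sample_id="gray0")


@pytest.fixture
def rgb_image(rng):
    return gn.ImageSample(pixels=rng.random((96, 96, 3)).astype(np.float32),
                          label=1, sample_id="rgb0")


@pytest.fixture
def ten_image_dataset(rng):
    """10 originals, 2 classes, distinct ids; used for split/leakage checks."""
    samples = [
        gn.ImageSample(pixels=rng.random((16, 16, 1)).astype(np.float32),
                       label=i % 2, sample_id=f"img{i:02d}")
        for i in range(10)
    ]
    return gn.LabeledDataset(samples=samples, class_names=["neg", "pos"])


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Smallest config the architecture admits; keeps model tests fast."""
    return gn.ModelConfig(variant="R3_R5_R35", input_shape=(32, 32, 1),
                          n_classes=2, base_width=8, head_hidden=8, seed=7)


@pytest.fixture
def tiny_model(tiny_model_cfg):
    return gn.build_model(tiny_model_cfg)


def numeric_grad(f, x, eps=1e-4):
    """Central-difference gradient of scalar f at ndarray x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
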