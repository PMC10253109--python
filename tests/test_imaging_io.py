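"""Image loading, normalization, balancing, augmentation and splitting."""

import imageio.v3 as iio
import numpy as np
import pytest

import granulonet as gn


# ---------------------------------------------------------------------------
# load_image
# ---------------------------------------------------------------------------

def test_load_image_normalizes_by_format_max(tmp_path):
    # 8-bit PNG with max 255 -> max 1.0
    arr8 = np.array([[0, 128], [64, 255]], dtype=np.uint8)
    iio.imwrite(tmp_path / "a.png", arr8)
    s = gn.load_image(tmp_path / "a.png", channels=1)
    assert s.pixels.max() == pytest.approx(1.0)
    assert s.pixels[0, 1, 0] == pytest.approx(128 / 255)

    # 16-bit TIFF with max 65535 -> max 1.0 (hand-built 2x2 fixture)
    arr16 = np.array([[0, 1000], [30000, 65535]], dtype=np.uint16)
    iio.imwrite(tmp_path / "b.tiff", arr16)
    s16 = gn.load_image(tmp_path / "b.tiff", channels=1)
    assert s16.pixels.max() == pytest.approx(1.0)
    assert s16.pixels[0, 1, 0] == pytest.approx(1000 / 65535)

    # all-zero image stays zero with no NaN
    iio.imwrite(tmp_path / "z.png", np.zeros((4, 4), dtype=np.uint8))
    z = gn.load_image(tmp_path / "z.png", channels=3)
    assert np.all(z.pixels == 0) and not np.isnan(z.pixels).any()
    assert z.pixels.shape == (4, 4, 3)  # grayscale replicated


def test_load_image_errors(tmp_path):
    with pytest.raises(IOError):
        gn.load_image(tmp_path / "missing.png")
    bad = tmp_path / "bad.png"
    bad.write_bytes(b"not an image at all")
    with pytest.raises(IOError):
        gn.load_image(bad)


def test_normalization_idempotent(tmp_path, rng):
    arr = (rng.random((8, 8)) * 255).astype(np.uint8)
    iio.imwrite(tmp_path / "x.png", arr)
    s = gn.load_image(tmp_path / "x.png", channels=1)
    # re-normalizing already-[0,1] float data is the identity (clip no-op)
    assert np.array_equal(np.clip(s.pixels, 0, 1), s.pixels)


# ---------------------------------------------------------------------------
# resize_cubic
# ---------------------------------------------------------------------------

def test_resize_cubic_shapes_and_constants(gray_image):
    out = gn.resize_cubic(gray_image, (224, 224))
    assert out.pixels.shape == (224, 224, 1)
    assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    const = gn.ImageSample(pixels=np.full((50, 40, 1), 0.3, np.float32),
                           label=0, sample_id="c")
    out = gn.resize_cubic(const, (64, 32))
    assert np.allclose(out.pixels, 0.3, atol=1e-5)

    same = gn.resize_cubic(gray_image, gray_image.pixels.shape[:2])
    assert np.array_equal(same.pixels, gray_image.pixels)

    with pytest.raises(ValueError):
        gn.resize_cubic(gray_image, (4, 64))


# ---------------------------------------------------------------------------
# balance_classes
# ---------------------------------------------------------------------------

def test_balance_downsamples_to_minority_count(rng):
    # mimic an unbalanced 3-class corpus (133 / 487 / 210 -> 133 each)
    counts = [133, 487, 210]
    samples = []
    for c, n in enumerate(counts):
        for i in range(n):
            samples.append(gn.ImageSample(
                pixels=np.zeros((8, 8, 1), np.float32), label=c,
                sample_id=f"s{c}_{i}"))
    ds = gn.LabeledDataset(samples=samples,
                           class_names=["normal", "benign", "malignant"])
    out = gn.balance_classes(ds, seed=4)
    assert out.class_counts().tolist() == [133, 133, 133]

    # determinism and the already-balanced identity
    out2 = gn.balance_classes(ds, seed=4)
    assert [s.sample_id for s in out.samples] == [s.sample_id for s in out2.samples]
    rebalanced = gn.balance_classes(out, seed=9)
    assert sorted(s.sample_id for s in rebalanced.samples) == \
        sorted(s.sample_id for s in out.samples)


def test_balance_rejects_empty_class():
    ds = gn.LabeledDataset(
        samples=[gn.ImageSample(pixels=np.zeros((4, 4, 1), np.float32),
                                label=0, sample_id="a")],
        class_names=["x", "y"])
    with pytest.raises(ValueError):
        gn.balance_classes(ds, seed=0)


# ---------------------------------------------------------------------------
# augment_triple
# ---------------------------------------------------------------------------

def test_augmentation_triples_and_preserves_labels(ten_image_dataset):
    out = gn.augment_triple(ten_image_dataset, shift_frac=0.1, seed=3)
    assert len(out) == 3 * len(ten_image_dataset)
    by_origin = {}
    for s in out.samples:
        by_origin.setdefault(s.origin_id, []).append(s)
    for origin, group in by_origin.items():
        assert len(group) == 3
        assert len({s.label for s in group}) == 1
        augmented = [s for s in group if s.source_group == "augmented"]
        assert all(s.parent_id == origin for s in augmented)


def test_zero_shift_copy_equals_original_and_flip_is_involution(ten_image_dataset):
    out = gn.augment_triple(ten_image_dataset, shift_frac=0.0, seed=0)
    for i in range(0, len(out.samples), 3):
        orig, shifted, flipped = out.samples[i:i + 3]
        assert np.array_equal(shifted.pixels, orig.pixels)
        assert np.array_equal(flipped.pixels[:, ::-1], orig.pixels)


# ---------------------------------------------------------------------------
# split_train_test
# ---------------------------------------------------------------------------

def test_split_is_group_aware_and_leak_free(ten_image_dataset):
    aug = gn.augment_triple(ten_image_dataset, seed=1)
    for seed in range(5):  # exhaustive id check across several seeds
        train, test = gn.split_train_test(aug, 0.8, seed=seed)
        train_ids = {s.sample_id for s in train.samples}
        test_ids = {s.sample_id for s in test.samples}
        assert not train_ids & test_ids
        assert all(s.source_group == "original" for s in test.samples)
        test_origins = {s.origin_id for s in test.samples}
        train_origins = {s.origin_id for s in train.samples}
        assert not test_origins & train_origins
        # stratified: 8 train / 2 test originals, one test original per class
        assert len(test.samples) == 2
        assert sorted(s.label for s in test.samples) == [0, 1]


def test_split_reproducible_and_validates(ten_image_dataset):
    a = gn.split_train_test(ten_image_dataset, 0.8, seed=11)
    b = gn.split_train_test(ten_image_dataset, 0.8, seed=11)
    assert [s.sample_id for s in a[0].samples] == [s.sample_id for s in b[0].samples]
    assert [s.sample_id for s in a[1].samples] == [s.sample_id for s in b[1].samples]

    single = gn.LabeledDataset(
        samples=[gn.ImageSample(pixels=np.zeros((4, 4, 1), np.float32),
                                label=0, sample_id="only"),
                 gn.ImageSample(pixels=np.zeros((4, 4, 1), np.float32),
                                label=1, sample_id="o1"),
                 gn.ImageSample(pixels=np.zeros((4, 4, 1), np.float32),
                                label=1, sample_id="o2")],
        class_names=["a", "b"])
    with pytest.raises(ValueError):
        gn.split_train_test(single, 0.8, seed=0)  # class "a" has 1 original
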