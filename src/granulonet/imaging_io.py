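"""Reading, preprocessing, balancing, augmenting and splitting image datasets.

The pipeline mirrors the standard preparation of small medical-imaging
corpora: pixel values are normalized to [0, 1], images are resized with
cubic interpolation, classes are equalized by random down-sampling,
augmentation triples each image (original + a random width/height shift
+ a horizontal flip), and the train/test split is stratified and
group-aware so an augmented copy never lands on the opposite side of the
split from its source image.  The test side keeps original images only.

All randomness is driven by an explicit integer seed per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageSample",
    "LabeledDataset",
    "load_image",
    "load_manifest",
    "resize_cubic",
    "balance_classes",
    "augment_triple",
    "split_train_test",
]

ORIGINAL = "original"


@dataclass
class ImageSample:
    """One labeled image: float32 pixels (H, W, C) in [0, 1]."""

    pixels: np.ndarray
    label: int
    sample_id: str
    source_group: str = ORIGINAL  # "original" or "augmented"
    parent_id: str | None = None  # set for augmented samples

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ValueError("pixels must be (H, W, C) with C in {1, 3}")
        if self.source_group != ORIGINAL and not self.parent_id:
            raise ValueError("augmented samples must record their parent id")

    @property
    def origin_id(self) -> str:
        """The original image this sample descends from (itself if original)."""
        return self.parent_id if self.parent_id else self.sample_id


@dataclass
class LabeledDataset:
    samples: list[ImageSample] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    split_tag: str = "none"

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique within a dataset")
        k = len(self.class_names)
        if any(s.label < 0 or s.label >= k for s in self.samples):
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))

    def manifest(self) -> pd.DataFrame:
        """Tabular view (sample_id, label, source_group, parent_id)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "label": [s.label for s in self.samples],
                "class_name": [self.class_names[s.label] for s in self.samples],
                "source_group": [s.source_group for s in self.samples],
                "parent_id": [s.parent_id or "" for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# Loading and resizing
# ---------------------------------------------------------------------------

_FORMAT_MAX = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def load_image(path: str | Path, channels: int = 3,
               label: int = 0, sample_id: str | None = None) -> ImageSample:
    """Read a PNG/JPEG/TIFF file into a normalized ImageSample.

    Integer pixel data is divided by the format's maximum representable
    value (255 for 8-bit, 65535 for 16-bit); float input is assumed to be
    already scaled and is clipped to [0, 1].  Grayscale images are
    replicated across channels when ``channels=3``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot decode image file: {path}") from exc
    if arr.dtype in _FORMAT_MAX:
        pixels = arr.astype(np.float32) / _FORMAT_MAX[arr.dtype]
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = np.clip(arr.astype(np.float32), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported pixel bit depth {arr.dtype} in {path}")
    if pixels.ndim == 2:
        pixels = pixels[:, :, None]
    if pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    if channels == 3 and pixels.shape[2] == 1:
        pixels = np.repeat(pixels, 3, axis=2)
    elif channels == 1 and pixels.shape[2] == 3:
        pixels = pixels.mean(axis=2, keepdims=True)
    return ImageSample(pixels=pixels, label=label,
                       sample_id=sample_id or path.stem)


def load_manifest(csv_path: str | Path, class_names: list[str],
                  channels: int = 3, root: str | Path | None = None) -> LabeledDataset:
    """Load a dataset from a CSV manifest with columns sample_id, path, label."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    root = Path(root) if root is not None else csv_path.parent
    samples = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        samples.append(load_image(p, channels=channels, label=int(row.label),
                                  sample_id=str(row.sample_id)))
    return LabeledDataset(samples=samples, class_names=list(class_names))


def resize_cubic(img: ImageSample, target: tuple[int, int]) -> ImageSample:
    """Resize with cubic interpolation; overshoot is clipped back to [0, 1]."""
    th, tw = target
    if th < 8 or tw < 8:
        raise ValueError(f"target dims must be >= 8, got {target}")
    if img.pixels.shape[:2] == (th, tw):
        return replace(img, pixels=img.pixels.copy())
    out = _sk_resize(img.pixels, (th, tw), order=3, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return replace(img, pixels=np.clip(out, 0.0, 1.0).astype(np.float32))


# ---------------------------------------------------------------------------
# Balancing, augmentation, splitting
# ---------------------------------------------------------------------------

def balance_classes(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Down-sample every class to the minority-class count, without replacement."""
    counts = ds.class_counts()
    if (counts == 0).any():
        empty = [ds.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"cannot balance: empty class(es) {empty}")
    n_keep = int(counts.min())
    rng = np.random.default_rng(seed)
    labels = ds.labels
    keep_idx: list[int] = []
    for c in range(len(ds.class_names)):
        idx = np.flatnonzero(labels == c)
        keep_idx.extend(rng.choice(idx, size=n_keep, replace=False))
    keep_idx.sort()
    return LabeledDataset(samples=[ds.samples[i] for i in keep_idx],
                          class_names=list(ds.class_names),
                          split_tag=ds.split_tag)


def _shift_edge_pad(pixels: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate by (dy, dx) pixels, filling exposed borders by edge replication."""
    h, w = pixels.shape[:2]
    pad_y = abs(dy)
    pad_x = abs(dx)
    padded = np.pad(pixels, ((pad_y, pad_y), (pad_x, pad_x), (0, 0)), mode="edge")
    y0 = pad_y - dy
    x0 = pad_x - dx
    return padded[y0:y0 + h, x0:x0 + w]


def augment_triple(ds: LabeledDataset, shift_frac: float = 0.1,
                   seed: int = 0) -> LabeledDataset:
    """Triple the dataset: original + random shift + horizontal flip.

    The shifted copy is translated by a uniform offset in +/- shift_frac
    of each dimension (edge replication fills the border); the flipped
    copy mirrors left-right.  Augmented samples keep their label and
    record the parent sample_id.
    """
    if not 0.0 <= shift_frac < 0.5:
        raise ValueError("shift_frac must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out: list[ImageSample] = []
    for s in ds.samples:
        h, w = s.pixels.shape[:2]
        dy = int(round(rng.uniform(-shift_frac, shift_frac) * h))
        dx = int(round(rng.uniform(-shift_frac, shift_frac) * w))
        out.append(s)
        out.append(ImageSample(pixels=_shift_edge_pad(s.pixels, dy, dx),
                               label=s.label, sample_id=f"{s.sample_id}#shift",
                               source_group="augmented", parent_id=s.sample_id))
        out.append(ImageSample(pixels=s.pixels[:, ::-1].copy(),
                               label=s.label, sample_id=f"{s.sample_id}#flip",
                               source_group="augmented", parent_id=s.sample_id))
    return LabeledDataset(samples=out, class_names=list(ds.class_names),
                          split_tag=ds.split_tag)


def split_train_test(ds: LabeledDataset, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, group-aware train/test split at the original-image level.

    Originals are partitioned per class; an original carries all its
    augmented children to the training side, while children of test-side
    originals are discarded so the test set contains unmodified images
    only and no information leaks across the split.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    originals = [s for s in ds.samples if s.source_group == ORIGINAL]
    by_class: dict[int, list[str]] = {}
    for s in originals:
        by_class.setdefault(s.label, []).append(s.sample_id)
    test_ids: set[str] = set()
    train_ids: set[str] = set()
    for c in sorted(by_class):
        ids = by_class[c]
        if len(ids) < 2:
            raise ValueError(
                f"class {ds.class_names[c]!r} has fewer than 2 original images")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty
        train_ids.update(ids[i] for i in perm[:n_train])
        test_ids.update(ids[i] for i in perm[n_train:])
    train_samples = [s for s in ds.samples if s.origin_id in train_ids]
    test_samples = [s for s in ds.samples
                    if s.origin_id in test_ids and s.source_group == ORIGINAL]
    train = LabeledDataset(samples=train_samples, class_names=list(ds.class_names),
                           split_tag="train")
    test = LabeledDataset(samples=test_samples, class_names=list(ds.class_names),
                          split_tag="test")
    return train, test
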