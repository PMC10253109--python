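"""Synthetic medical-style image generators for end-to-end testing.

Two styles emulate the statistical structure of the real corpora the
pipeline targets, without any downloads:

* ``ultrasound`` — grayscale images with multiplicative speckle texture
  (gamma-distributed, lightly smoothed), optionally containing a darker
  lesion: a smooth-edged ellipse for the "benign" class, an
  irregular-edged region (an ellipse with angular radius perturbation)
  for "malignant".  In the binary scheme class 0 is lesion-free and
  class 1 carries a lesion.
* ``histopath`` — small pink-ish RGB patches with dark round nucleus-like
  blobs whose mean density differs between classes.

A single ``separability`` knob in [0, 1] scales every class-conditional
difference (lesion contrast, edge irregularity, blob-density gap).  At
separability 0 all classes are drawn from the identical distribution, so
labels carry no information; at 1 the classes are cleanly separable.
Generation is a pure function of (spec, seed): the same spec yields a
bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_io import ImageSample, LabeledDataset
from .train_eval import ConfusionMatrix

__all__ = ["SyntheticSpec", "generate_dataset", "write_dataset",
           "worked_example_confusion"]

# fixed shape parameters of the phantoms (documented defaults, not knobs)
_SPECKLE_LOOKS = 4.0          # gamma shape of the speckle; lower = grainier
_SPECKLE_SMOOTH = 1.0         # gaussian sigma applied to the speckle field
_BASE_INTENSITY = 0.45        # mean background brightness, ultrasound
_LESION_CONTRAST = 0.55       # max fractional darkening inside a lesion
_LESION_EDGE_SIGMA = 2.0      # edge softness of the benign ellipse (px)
_IRREGULARITY = 0.35          # angular radius perturbation, malignant
_HISTO_BASE = np.array([0.88, 0.72, 0.83])  # pink-ish background RGB
_BLOB_COLOR = np.array([0.35, 0.20, 0.45])  # dark purple nuclei
_BLOB_RADIUS = (2.0, 4.0)     # nucleus radius range (px at 50 x 50)
_BLOB_BASE_COUNT = 8.0        # mean nuclei per negative patch
_BLOB_EXTRA_COUNT = 18.0      # extra mean nuclei at separability 1


@dataclass
class SyntheticSpec:
    style: str = "ultrasound"  # ultrasound | histopath
    n_per_class: int = 50
    image_size: tuple[int, int] = (64, 64)
    n_classes: int = 2
    separability: float = 1.0
    noise_level: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.style not in ("ultrasound", "histopath"):
            raise ValueError("style must be 'ultrasound' or 'histopath'")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def class_names(self) -> list[str]:
        if self.style == "histopath":
            return ["idc_negative", "idc_positive"][: self.n_classes] \
                if self.n_classes == 2 else ["negative", "low", "high"]
        return (["normal", "abnormal"] if self.n_classes == 2
                else ["normal", "benign", "malignant"])


# ---------------------------------------------------------------------------
# Ultrasound-style phantoms
# ---------------------------------------------------------------------------

def _speckle_background(shape, rng: np.random.Generator,
                        noise_level: float) -> np.ndarray:
    field = rng.gamma(_SPECKLE_LOOKS, 1.0 / _SPECKLE_LOOKS, size=shape)
    field = gaussian_filter(field, _SPECKLE_SMOOTH)
    img = _BASE_INTENSITY * (1.0 + noise_level * (field - field.mean()))
    return img


def _lesion_mask(shape, rng: np.random.Generator, irregular: float) -> np.ndarray:
    """Soft [0,1] mask of an elliptical lesion, optionally irregular-edged."""
    h, w = shape
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    ry = rng.uniform(0.12, 0.22) * h
    rx = rng.uniform(0.12, 0.22) * w
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    y0, x0 = yy - cy, xx - cx
    yr = y0 * np.cos(theta) - x0 * np.sin(theta)
    xr = y0 * np.sin(theta) + x0 * np.cos(theta)
    if irregular > 0:
        # perturb the radius as a low-order harmonic of the polar angle
        ang = np.arctan2(yr, xr)
        n_lobes = rng.integers(4, 8)
        phase = rng.uniform(0, 2 * np.pi)
        wobble = 1.0 + irregular * np.sin(n_lobes * ang + phase)
    else:
        wobble = 1.0
    r = np.sqrt((yr / ry) ** 2 + (xr / rx) ** 2) / wobble
    mask = (r <= 1.0).astype(np.float64)
    return gaussian_filter(mask, _LESION_EDGE_SIGMA)


def _ultrasound_image(rng: np.random.Generator, spec: SyntheticSpec,
                      label: int) -> np.ndarray:
    img = _speckle_background(spec.image_size, rng, spec.noise_level)
    # one rng draw pattern per sample regardless of class: the lesion
    # geometry is always sampled, its visibility scales with separability
    if spec.n_classes == 2:
        irregular = _IRREGULARITY * spec.separability * (rng.random() < 0.5)
        contrast = _LESION_CONTRAST * spec.separability * (label == 1)
    else:
        irregular = _IRREGULARITY * spec.separability * (label == 2)
        contrast = _LESION_CONTRAST * spec.separability * (label > 0)
    mask = _lesion_mask(spec.image_size, rng, float(irregular))
    img = img * (1.0 - contrast * mask)
    return np.clip(img, 0.0, 1.0)[:, :, None].astype(np.float32)


# ---------------------------------------------------------------------------
# Histopathology-style patches
# ---------------------------------------------------------------------------

def _histopath_image(rng: np.random.Generator, spec: SyntheticSpec,
                     label: int) -> np.ndarray:
    h, w = spec.image_size
    img = np.ones((h, w, 3)) * _HISTO_BASE
    img += rng.normal(0, 0.03 * spec.noise_level, size=img.shape)
    if spec.n_classes == 2:
        frac = float(label)
    else:
        frac = label / 2.0
    lam = _BLOB_BASE_COUNT + _BLOB_EXTRA_COUNT * spec.separability * frac
    lam *= (h * w) / (50.0 * 50.0)  # density defined at the native 50x50 scale
    n_blobs = rng.poisson(lam)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(*_BLOB_RADIUS) * (h / 50.0)
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r ** 2
        blob = np.exp(-0.5 * d2 * 4)
        img = img * (1 - blob[:, :, None]) + blob[:, :, None] * _BLOB_COLOR
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a balanced labeled dataset; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    render = _ultrasound_image if spec.style == "ultrasound" else _histopath_image
    samples = []
    # interleave classes so truncated prefixes stay roughly balanced
    for i in range(spec.n_per_class):
        for label in range(spec.n_classes):
            pixels = render(rng, spec, label)
            samples.append(ImageSample(
                pixels=pixels, label=label,
                sample_id=f"{spec.style}-{spec.seed}-{label}-{i:04d}"))
    return LabeledDataset(samples=samples, class_names=spec.class_names)


def write_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write PNGs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ds.samples:
        fname = f"{s.sample_id}.png"
        arr = (np.clip(s.pixels, 0, 1) * 255).round().astype(np.uint8)
        iio.imwrite(out_dir / fname, arr.squeeze())
        rows.append((s.sample_id, fname, s.label))
    manifest = out_dir / "manifest.csv"
    import pandas as pd
    pd.DataFrame(rows, columns=["sample_id", "path", "label"]).to_csv(
        manifest, index=False)
    return manifest


def worked_example_confusion() -> ConfusionMatrix:
    """The published binary test confusion matrix used as a metrics fixture.

    68 evaluated cases: 33 true negatives, 30 true positives, 4 false
    positives and 1 false negative (5 errors in total).
    """
    return ConfusionMatrix(counts=np.array([[33, 4], [1, 30]]),
                           class_names=["0", "1"])
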