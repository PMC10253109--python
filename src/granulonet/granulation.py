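"""Granular-computing preprocessing: tile, featurize, aggregate, highlight.

An image is cut into fixed-size square granules on a regular grid
(default 32 x 32, row-major, trailing partial tiles dropped), a feature
vector is extracted per granule by a pluggable backbone, and the per-
granule vectors are either aggregated into one descriptor for the whole
image (``vector`` mode) or turned into a per-granule saliency weighting
that rescales the image itself (``highlight`` mode).  Highlight mode
produces an image of the original shape and is the form consumed by the
classification network; vector mode yields a fixed-length descriptor
usable by any conventional classifier.

Backbones are callables mapping a (g, g, C) tile to a fixed-length 1-D
vector.  Two deterministic backbones ship with the package:

* :class:`TileStatsBackbone` — per-channel mean / standard deviation /
  gradient energy (d = 3C), fast and fully interpretable;
* :class:`RandomConvBackbone` — a small frozen convolutional feature
  extractor with weights drawn once from a fixed seed.

Any richer extractor (e.g. an ImageNet-pretrained truncated CNN) can be
plugged in through the same callable contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging_io import ImageSample

__all__ = [
    "GranuleGrid",
    "GranuleFeatures",
    "granulate",
    "extract_granule_features",
    "aggregate_features",
    "highlight_image",
    "reassemble",
    "TileStatsBackbone",
    "RandomConvBackbone",
    "get_backbone",
    "SALIENCY_FLOOR",
]

#: Lower bound of the min-max rescaled saliency in highlight mode; keeps
#: low-saliency tissue visible instead of zeroing it out.
SALIENCY_FLOOR = 0.2


@dataclass
class GranuleGrid:
    """Row-major, non-overlapping square tiles cut from one image."""

    granules: np.ndarray  # (n, g, g, C)
    grid_rows: int
    grid_cols: int
    granule_size: int
    origin_coords: list[tuple[int, int]]  # top-left (row, col) per tile

    def __post_init__(self):
        if len(self.granules) != self.grid_rows * self.grid_cols:
            raise ValueError("granule count must equal grid_rows * grid_cols")

    def __len__(self) -> int:
        return len(self.granules)


@dataclass
class GranuleFeatures:
    per_granule: np.ndarray          # (n_granules, d)
    aggregated: np.ndarray | None    # (d,) once aggregate_features has run
    aggregation_mode: str | None
    backbone_id: str


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class TileStatsBackbone:
    """Per-channel mean, standard deviation and mean gradient magnitude."""

    backbone_id = "tile_stats"

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        tile = np.asarray(tile, dtype=np.float64)
        gy, gx = np.gradient(tile, axis=(0, 1))
        grad = np.sqrt(gy ** 2 + gx ** 2)
        feats = np.concatenate([
            tile.mean(axis=(0, 1)),
            tile.std(axis=(0, 1)),
            grad.mean(axis=(0, 1)),
        ])
        return feats.astype(np.float32)


class RandomConvBackbone:
    """A frozen random convolutional feature extractor.

    Two 3x3 valid convolutions with ReLU, weights drawn once from a fixed
    seed, followed by per-filter global mean and max.  Deterministic for
    a given (seed, n_filters) and usable at any tile size >= 5.
    """

    def __init__(self, seed: int = 0, n_filters: int = 8, channels: int = 1):
        rng = np.random.default_rng(seed)
        self.backbone_id = f"random_conv(seed={seed},f={n_filters})"
        self.w1 = rng.normal(0, np.sqrt(2.0 / (9 * channels)),
                             (n_filters, channels, 3, 3)).astype(np.float32)
        self.w2 = rng.normal(0, np.sqrt(2.0 / (9 * n_filters)),
                             (n_filters, n_filters, 3, 3)).astype(np.float32)
        self.channels = channels

    @staticmethod
    def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        # x: (C, H, W); w: (F, C, 3, 3) -> (F, H-2, W-2)
        c, h, wd = x.shape
        ho, wo = h - 2, wd - 2
        cols = np.empty((c * 9, ho * wo), dtype=np.float32)
        idx = 0
        for ch in range(c):
            for ki in range(3):
                for kj in range(3):
                    cols[idx] = x[ch, ki:ki + ho, kj:kj + wo].ravel()
                    idx += 1
        return (w.reshape(w.shape[0], -1) @ cols).reshape(w.shape[0], ho, wo)

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        x = np.asarray(tile, dtype=np.float32)
        if x.ndim == 3:
            x = np.moveaxis(x, 2, 0)
        else:
            x = x[None]
        if x.shape[0] != self.channels:
            if x.shape[0] == 1:
                x = np.repeat(x, self.channels, axis=0)
            else:
                x = x.mean(axis=0, keepdims=True)
                x = np.repeat(x, self.channels, axis=0)
        h1 = np.maximum(self._conv_valid(x, self.w1), 0)
        h2 = np.maximum(self._conv_valid(h1, self.w2), 0)
        return np.concatenate([h2.mean(axis=(1, 2)), h2.max(axis=(1, 2))])


_BACKBONES = {
    "tile_stats": TileStatsBackbone,
    "random_conv": RandomConvBackbone,
}


def get_backbone(name: str, **kwargs):
    """Instantiate a shipped backbone by name ('tile_stats' or 'random_conv')."""
    try:
        return _BACKBONES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; "
                         f"available: {sorted(_BACKBONES)}") from None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def granulate(img: ImageSample, g: int = 32) -> GranuleGrid:
    """Cut an image into g x g tiles at stride g, row-major from (0, 0).

    Trailing rows/columns that do not fill a whole tile are dropped, so
    the grid has floor(H/g) x floor(W/g) granules.
    """
    if g < 4:
        raise ValueError("granule size must be >= 4")
    h, w = img.pixels.shape[:2]
    if g > min(h, w):
        raise ValueError(f"granule size {g} exceeds image dims {(h, w)}")
    rows, cols = h // g, w // g
    tiles = []
    coords = []
    for i in range(0, rows * g, g):
        for j in range(0, cols * g, g):
            tiles.append(img.pixels[i:i + g, j:j + g, :])
            coords.append((i, j))
    return GranuleGrid(granules=np.stack(tiles), grid_rows=rows, grid_cols=cols,
                       granule_size=g, origin_coords=coords)


def reassemble(grid: GranuleGrid) -> np.ndarray:
    """Stitch the tiles back into the (covered part of the) image."""
    g = grid.granule_size
    c = grid.granules.shape[-1]
    out = np.empty((grid.grid_rows * g, grid.grid_cols * g, c), dtype=np.float32)
    for tile, (i, j) in zip(grid.granules, grid.origin_coords):
        out[i:i + g, j:j + g] = tile
    return out


def extract_granule_features(grid: GranuleGrid, backbone) -> GranuleFeatures:
    """Apply the backbone to every granule; rows follow grid order."""
    feats = [np.asarray(backbone(tile), dtype=np.float32).ravel()
             for tile in grid.granules]
    d = feats[0].shape[0]
    if any(f.shape[0] != d for f in feats):
        raise ValueError("backbone returned vectors of differing length")
    return GranuleFeatures(per_granule=np.stack(feats), aggregated=None,
                           aggregation_mode=None,
                           backbone_id=getattr(backbone, "backbone_id",
                                               type(backbone).__name__))


def aggregate_features(gf: GranuleFeatures, mode: str = "mean") -> GranuleFeatures:
    """Collapse per-granule rows into one descriptor by mean or max pooling."""
    if gf.per_granule.size == 0:
        raise ValueError("no per-granule features to aggregate")
    if mode == "mean":
        agg = gf.per_granule.mean(axis=0, dtype=np.float64)
    elif mode == "max":
        agg = gf.per_granule.max(axis=0)
    else:
        raise ValueError(f"aggregation mode must be 'mean' or 'max', got {mode!r}")
    return GranuleFeatures(per_granule=gf.per_granule, aggregated=agg,
                           aggregation_mode=mode, backbone_id=gf.backbone_id)


def granule_saliency(gf: GranuleFeatures,
                     floor: float = SALIENCY_FLOOR) -> np.ndarray:
    """Per-granule saliency: L2 feature norms min-max rescaled to [floor, 1].

    When all norms coincide there is nothing to rank and every granule
    gets saliency 1 (a no-op weighting).
    """
    norms = np.linalg.norm(gf.per_granule.astype(np.float64), axis=1)
    lo, hi = norms.min(), norms.max()
    if hi - lo < 1e-12:
        return np.ones_like(norms)
    return floor + (1.0 - floor) * (norms - lo) / (hi - lo)


def highlight_image(img: ImageSample, gf: GranuleFeatures, g: int = 32,
                    floor: float = SALIENCY_FLOOR) -> ImageSample:
    """Rescale each granule's pixels by its saliency; shape is preserved.

    Pixels outside the tiled region (when dims are not divisible by g)
    are left untouched; the result is clipped to [0, 1].
    """
    grid = granulate(img, g)
    if len(grid) != gf.per_granule.shape[0]:
        raise ValueError("feature rows do not match the image's granule count")
    sal = granule_saliency(gf, floor=floor)
    out = img.pixels.copy()
    for s, (i, j) in zip(sal, grid.origin_coords):
        out[i:i + g, j:j + g] *= np.float32(s)
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def granulation_vector(img: ImageSample, backbone, g: int = 32,
                       mode: str = "mean") -> np.ndarray:
    """Convenience: granulate -> extract -> aggregate, returning the descriptor."""
    gf = extract_granule_features(granulate(img, g), backbone)
    return aggregate_features(gf, mode).aggregated


def granulation_highlight(img: ImageSample, backbone, g: int = 32,
                          floor: float = SALIENCY_FLOOR) -> ImageSample:
    """Convenience: granulate -> extract -> highlight, returning the image."""
    gf = extract_granule_features(granulate(img, g), backbone)
    return highlight_image(img, gf, g=g, floor=floor)
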