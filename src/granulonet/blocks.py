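"""Architectural building blocks: R-block, X-module, downsampling, attention.

The network is wide-and-deep in the GoogLeNet sense with residual units:

* **R-block** — two stacked convolutions with an additive shortcut.  The
  first convolution is followed by batch normalization and a learnable
  ReLU; the branch output is added to the input (identity shortcut when
  channel counts match, 1x1 projection otherwise).  Three filter-size
  variants exist: R3 (3x3, 3x3), R5 (5x5, 5x5) and R35 (3x3, 5x5).
* **X-module** — an inception-style unit: three parallel R-blocks, each
  preceded by a 1x1 channel reducer, plus a max-pool + 1x1 branch; the
  four branch outputs are concatenated on the channel axis.  Spatial
  resolution is preserved (same padding everywhere).
* **Downsample module** — the only place resolution drops: a 3x3
  stride-2 max pool concatenated with a 1x1-reduced 3x3 stride-2
  convolution, halving H and W (ceil) and widening channels.
* **Convolutional attention** — a k x k convolution followed by a 1x1
  convolution produces one scalar score per pixel; a softmax across all
  spatial positions turns the scores into a weight map summing to 1,
  which multiplies the input element-wise.  The product is rescaled by
  H*W so that a uniform map is exactly the identity.
* **Dense attention** — a per-position linear projection of the feature
  vector to a scalar score, spatial softmax, and a weighted sum of the
  feature vectors: attentive global pooling of a (H', W', C) map to C.
* **Learnable softmax head** — dense -> learnable sigmoid -> dense ->
  softmax, producing a probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (BatchNorm2d, Conv2d, Linear, Module, ModuleList, Tensor,
                       concat, conv2d, matmul, maxpool2d, mul, reshape,
                       softmax, tsum, upsample_nearest)
from .laf import LAFReLU, LAFSigmoid

__all__ = [
    "BlockSpec",
    "XModuleSpec",
    "AttentionMap",
    "RBlock",
    "XModule",
    "DownsampleModule",
    "ConvAttention",
    "DenseAttention",
    "LearnableSoftmaxHead",
    "VARIANT_FILTERS",
]

#: Filter-size pairs (conv1, conv2) of the three R-block kinds.
_KIND_FILTERS = {"R3": (3, 3), "R5": (5, 5), "R35": (3, 5)}

#: R-block kinds of the three X-module branches per architecture variant.
VARIANT_FILTERS = {
    "R3_R3_R3": ("R3", "R3", "R3"),
    "R5_R5_R5": ("R5", "R5", "R5"),
    "R3_R5_R35": ("R3", "R5", "R35"),
}


@dataclass
class BlockSpec:
    """Configuration of one R-block."""

    kind: str  # R3 | R5 | R35
    in_channels: int
    out_channels: int
    reduce_channels: int = 0  # width of the 1x1 reducer in front (0 = none)

    def __post_init__(self):
        if self.kind not in _KIND_FILTERS:
            raise ValueError(f"unknown R-block kind {self.kind!r}")
        if self.out_channels <= 0:
            raise ValueError("out_channels must be positive")

    @property
    def filters(self) -> tuple[int, int]:
        return _KIND_FILTERS[self.kind]


@dataclass
class XModuleSpec:
    """Configuration of one X-module (three R-block branches + pool branch)."""

    branch_specs: tuple[BlockSpec, BlockSpec, BlockSpec]
    pool_branch_channels: int
    variant_name: str

    @property
    def out_channels(self) -> int:
        return sum(b.out_channels for b in self.branch_specs) + self.pool_branch_channels

    @classmethod
    def for_variant(cls, variant: str, in_channels: int, branch_width: int,
                    use_reducers: bool = True) -> "XModuleSpec":
        if variant not in VARIANT_FILTERS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"available: {sorted(VARIANT_FILTERS)}")
        reduce = branch_width if use_reducers else 0
        branches = tuple(
            BlockSpec(kind=k, in_channels=in_channels, out_channels=branch_width,
                      reduce_channels=reduce)
            for k in VARIANT_FILTERS[variant]
        )
        return cls(branch_specs=branches, pool_branch_channels=branch_width,
                   variant_name=variant)


@dataclass
class AttentionMap:
    """A spatial weight field; non-negative and summing to 1."""

    weights: np.ndarray  # (H, W)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < 0).any():
            raise ValueError("attention weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must sum to 1")
        self.weights = w


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _ConvBNAct(Module):
    """conv -> batchnorm -> learnable ReLU, the recurring conv pattern."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = LAFReLU(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class RBlock(Module):
    """Residual unit: out = conv2(LAF_relu(BN(conv1(x)))) + shortcut(x).

    The shortcut is the identity when in/out channel counts match and a
    1x1 projection otherwise; spatial dims are preserved by same padding.
    With the residual branch zeroed and matching channels the block is
    exactly the identity map.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None,
                 allow_projection: bool = True):
        super().__init__()
        self.spec = spec
        k1, k2 = spec.filters
        cin = spec.reduce_channels or spec.in_channels
        self.reducer = (_ConvBNAct(spec.in_channels, spec.reduce_channels, 1, rng=rng)
                        if spec.reduce_channels else None)
        self.conv1 = Conv2d(cin, spec.out_channels, k1, rng=rng)
        self.bn1 = BatchNorm2d(spec.out_channels)
        self.act1 = LAFReLU(spec.out_channels)
        self.conv2 = Conv2d(spec.out_channels, spec.out_channels, k2, rng=rng)
        if cin != spec.out_channels:
            if not allow_projection:
                raise ValueError(
                    f"R-block channel mismatch {cin} -> {spec.out_channels} "
                    "with projection disabled")
            self.shortcut = Conv2d(cin, spec.out_channels, 1, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        if self.reducer is not None:
            x = self.reducer(x)
        h = self.conv2(self.act1(self.bn1(self.conv1(x))))
        sc = x if self.shortcut is None else self.shortcut(x)
        return h + sc


class XModule(Module):
    """Inception-style unit of three R-block branches plus a pool branch.

    Output channels = sum of the three R-block widths + pool branch width;
    spatial dims are unchanged.
    """

    def __init__(self, spec: XModuleSpec, rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        self.branches = ModuleList([RBlock(b, rng=rng) for b in spec.branch_specs])
        cin = spec.branch_specs[0].in_channels
        self.pool_proj = _ConvBNAct(cin, spec.pool_branch_channels, 1, rng=rng)

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x) for b in self.branches]
        pooled = maxpool2d(x, k=3, stride=1, padding=1)
        outs.append(self.pool_proj(pooled))
        if len({o.data.shape[2:] for o in outs}) != 1:
            raise RuntimeError("X-module branches produced differing spatial dims")
        return concat(outs, axis=1)


class DownsampleModule(Module):
    """Stride-2 stage: concat[max-pool 3x3 s2, 1x1-reduced 3x3 s2 conv].

    Halves H and W (ceil) and widens channels to
    in_channels + conv_branch_channels.
    """

    def __init__(self, in_channels: int, conv_channels: int,
                 reduce_channels: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        reduce_channels = reduce_channels or max(in_channels // 2, 1)
        self.reducer = _ConvBNAct(in_channels, reduce_channels, 1, rng=rng)
        self.conv = _ConvBNAct(reduce_channels, conv_channels, 3, stride=2, rng=rng)
        self.out_channels = in_channels + conv_channels

    def forward(self, x: Tensor) -> Tensor:
        pooled = maxpool2d(x, k=3, stride=2, padding=1)
        convd = self.conv(self.reducer(x))
        return concat([pooled, convd], axis=1)


class ConvAttention(Module):
    """Spatial attention over an image or feature map.

    A k x k convolution (stride s) followed by a 1x1 convolution yields a
    scalar score per position; a softmax across all positions makes the
    weights a probability distribution over the map.  The input is
    multiplied by weights * H*W so a uniform map leaves it unchanged.
    Returns the attended tensor and the per-sample weight maps.
    """

    def __init__(self, in_channels: int, k: int = 3, stride: int = 1,
                 hidden: int = 8, rng: np.random.Generator | None = None):
        super().__init__()
        self.stride = stride
        self.conv = Conv2d(in_channels, hidden, k, stride=stride, rng=rng)
        self.act = LAFReLU(hidden)
        self.score = Conv2d(hidden, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        h, w = x.data.shape[2:]
        scores = self.score(self.act(self.conv(x)))
        if self.stride > 1:
            scores = upsample_nearest(scores, self.stride, out_hw=(h, w))
        weights = softmax(scores, axis=(2, 3))  # (N, 1, H, W), sums to 1
        attended = mul(x, mul(weights, float(h * w)))
        return attended, weights.data[:, 0]

    @staticmethod
    def attention_map(weights: np.ndarray, index: int = 0) -> AttentionMap:
        """Wrap one sample's weight field in a validated AttentionMap."""
        return AttentionMap(weights=weights[index])


class DenseAttention(Module):
    """Attentive pooling of a (N, C, H', W') map to (N, C).

    Each position's feature vector is projected to a scalar score by a
    dense layer (a 1x1 convolution); the softmax over positions weights
    the convex combination of feature vectors.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.score = Conv2d(channels, 1, 1, rng=rng)

    def forward(self, f: Tensor) -> tuple[Tensor, np.ndarray]:
        scores = self.score(f)                     # (N, 1, H, W)
        weights = softmax(scores, axis=(2, 3))
        pooled = tsum(mul(f, weights), axis=(2, 3))  # (N, C)
        return pooled, weights.data[:, 0]


class LearnableSoftmaxHead(Module):
    """Classifier head: dense -> learnable sigmoid -> dense -> softmax."""

    def __init__(self, in_features: int, n_classes: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.act = LAFSigmoid(hidden)
        self.fc2 = Linear(hidden, n_classes, rng=rng)

    def forward(self, v: Tensor) -> Tensor:
        logits = self.fc2(self.act(self.fc1(v)))
        return softmax(logits, axis=1)
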