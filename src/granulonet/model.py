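"""The full classification network: attention, X-module stages, aux heads.

Layer sequence (spatial resolution in parentheses for a 64 x 64 input):

    input (64)
    -> convolutional attention (64)
    -> 3x3 convolution + BN + learnable ReLU, stride-2 max pool (32)
    -> 2 X-modules (32)            -> downsample (16) -> aux classifier 1
    -> 3 X-modules (16)            -> downsample (8)  -> aux classifier 2
    -> 1 X-module (8)
    -> dense-layer attention (attentive global pooling to a vector)
    -> dropout
    -> learnable softmax head (main output)

All six X-modules use the filter-size configuration selected by the
architecture variant (``R3_R3_R3``, ``R5_R5_R5`` or ``R3_R5_R35``).  The
auxiliary classifiers (global average pool -> learnable softmax head)
tap the feature maps right after each downsample stage and supply
intermediate supervision during training; inference uses the main head.

Channel widths scale with ``base_width`` w: the stem convolution has w
channels and the X-module branch width starts at w/2, doubling after
each downsample.  The dense attention performs the attentive pooling
itself, so it is applied directly to the last X-module's map and the
pooled vector feeds dropout and the head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Module, ModuleList, Tensor, global_avg_pool, maxpool2d
from .blocks import (ConvAttention, DenseAttention, DownsampleModule,
                     LearnableSoftmaxHead, XModule, XModuleSpec, _ConvBNAct,
                     VARIANT_FILTERS)
from .autograd import Dropout

__all__ = ["ModelConfig", "ModelOutputs", "GranuloNet", "build_model",
           "count_parameters", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    variant: str = "R3_R5_R35"
    input_shape: tuple[int, int, int] = (224, 224, 3)  # (H, W, C)
    n_classes: int = 2
    base_width: int = 64
    dropout_rate: float = 0.5
    aux_enabled: bool = True
    attention_kernel: int = 3
    attention_stride: int = 1
    head_hidden: int = 32
    use_reducers: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANT_FILTERS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        h, w, c = self.input_shape
        if h < 16 or w < 16:
            raise ValueError("input must be at least 16 x 16 for two downsamples")
        if c not in (1, 3):
            raise ValueError("input channels must be 1 or 3")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile: 64 x 64 input, base width 16."""
        defaults = dict(input_shape=(64, 64, 3), base_width=16)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ModelOutputs:
    """Per-sample class probabilities from the main and auxiliary heads."""

    main: np.ndarray
    aux1: np.ndarray | None = None
    aux2: np.ndarray | None = None
    # live graph tensors, populated during training forward passes
    tensors: dict = field(default_factory=dict, repr=False)


class GranuloNet(Module):
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w, c_in = cfg.input_shape
        wbase = cfg.base_width
        bw1 = max(wbase // 2, 1)  # stage-1 X-module branch width

        self.attention = ConvAttention(c_in, k=cfg.attention_kernel,
                                       stride=cfg.attention_stride,
                                       hidden=max(wbase // 2, 4), rng=rng)
        # stem: conv + stride-2 max pool before the X-module stages
        self.stem = _ConvBNAct(c_in, wbase, 3, rng=rng)

        def stage(n_modules: int, cin: int, branch_width: int):
            mods = []
            for _ in range(n_modules):
                spec = XModuleSpec.for_variant(cfg.variant, cin, branch_width,
                                               use_reducers=cfg.use_reducers)
                mods.append(XModule(spec, rng=rng))
                cin = spec.out_channels
            return ModuleList(mods), cin

        self.stage1, c = stage(2, wbase, bw1)
        self.down1 = DownsampleModule(c, conv_channels=c, rng=rng)
        c = self.down1.out_channels
        self.aux1_head = LearnableSoftmaxHead(c, cfg.n_classes,
                                              hidden=cfg.head_hidden, rng=rng)
        self.stage2, c = stage(3, c, bw1 * 2)
        self.down2 = DownsampleModule(c, conv_channels=c, rng=rng)
        c = self.down2.out_channels
        self.aux2_head = LearnableSoftmaxHead(c, cfg.n_classes,
                                              hidden=cfg.head_hidden, rng=rng)
        self.stage3, c = stage(1, c, bw1 * 4)
        self.dense_attention = DenseAttention(c, rng=rng)
        self.dropout = Dropout(cfg.dropout_rate, seed=cfg.seed + 1)
        self.head = LearnableSoftmaxHead(c, cfg.n_classes,
                                         hidden=cfg.head_hidden, rng=rng)
        self.feature_channels = c

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor, return_attention: bool = False):
        cfg = self.cfg
        expected = (cfg.input_shape[2], cfg.input_shape[0], cfg.input_shape[1])
        if x.data.ndim != 4 or x.data.shape[1:] != expected:
            raise ValueError(
                f"batch shape {x.data.shape} does not match config "
                f"(N, {expected[0]}, {expected[1]}, {expected[2]})")
        x, conv_att = self.attention(x)
        h = maxpool2d(self.stem(x), k=3, stride=2, padding=1)
        for m in self.stage1:
            h = m(h)
        h = self.down1(h)
        aux1 = (self.aux1_head(global_avg_pool(h))
                if cfg.aux_enabled else None)
        for m in self.stage2:
            h = m(h)
        h = self.down2(h)
        aux2 = (self.aux2_head(global_avg_pool(h))
                if cfg.aux_enabled else None)
        for m in self.stage3:
            h = m(h)
        pooled, dense_att = self.dense_attention(h)
        pooled = self.dropout(pooled)
        main = self.head(pooled)
        out = ModelOutputs(
            main=main.data,
            aux1=None if aux1 is None else aux1.data,
            aux2=None if aux2 is None else aux2.data,
            tensors={"main": main, "aux1": aux1, "aux2": aux2},
        )
        if return_attention:
            out.tensors["conv_attention_map"] = conv_att
            out.tensors["dense_attention_map"] = dense_att
        return out


def build_model(cfg: ModelConfig) -> GranuloNet:
    """Construct the network for a configuration (validated by ModelConfig)."""
    return GranuloNet(cfg)


def forward(model: GranuloNet, batch: np.ndarray) -> ModelOutputs:
    """Run a batch of images (N, H, W, C) or (N, C, H, W) through the model."""
    batch = np.asarray(batch, dtype=np.float32)
    h, w, c = model.cfg.input_shape
    if batch.shape[1:] == (h, w, c):
        batch = np.moveaxis(batch, 3, 1)
    return model(Tensor(batch))


def count_parameters(model: Module) -> int:
    """Total trainable scalar count, including every LAF's (a, b, W)."""
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: GranuloNet, path: str | Path) -> None:
    """Write weights, batch-norm statistics and the config to an .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    cfg = asdict(model.cfg)
    cfg["input_shape"] = list(cfg["input_shape"])
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> GranuloNet:
    """Rebuild a model from a checkpoint; forward outputs reproduce bit-exactly."""
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        model = GranuloNet(ModelConfig(**cfg_dict))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
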