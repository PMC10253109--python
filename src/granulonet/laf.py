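"""Parametric learnable activation functions (LAFs).

A LAF wraps a fixed nonlinearity F in a trainable affine envelope,

    LAF(x; a, b, W) = a * F(W * x) + b,

where ``a`` (scale), ``b`` (shift) and ``W`` (input gain) are learned by
backpropagation alongside the network weights.  Two instances are used:

* ``laf_relu``    — F = max(0, .), placed after convolutional layers;
* ``laf_sigmoid`` — F = logistic, placed inside dense layers.

With the default initialization (a=1, b=0, W=1) both reduce exactly to
their classical counterparts, so training starts from a standard network
and the activations deform only if the data rewards it.

The module exposes a plain-ndarray functional API with closed-form
gradients (``laf_relu_grads`` / ``laf_sigmoid_grads``) and two trainable
layers (:class:`LAFReLU`, :class:`LAFSigmoid`) for use inside models.
Layers learn one (a, b, W) triple per feature channel by default; a
single shared triple is available with ``per_channel=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import DTYPE, Module, Tensor, _needs_grad, _unbroadcast, stable_sigmoid

__all__ = [
    "LAFParams",
    "laf_relu",
    "laf_sigmoid",
    "laf_relu_grads",
    "laf_sigmoid_grads",
    "LAFReLU",
    "LAFSigmoid",
]


@dataclass
class LAFParams:
    """The learnable triple parameterizing one activation function.

    Each field may be a scalar or a per-channel vector; the defaults make
    the LAF coincide with the classical activation.
    """

    a: float | np.ndarray = 1.0
    b: float | np.ndarray = 0.0
    W: float | np.ndarray = 1.0

    def __post_init__(self):
        for name in ("a", "b", "W"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"LAF parameter {name!r} must be finite")


# ---------------------------------------------------------------------------
# Functional API (plain ndarrays)
# ---------------------------------------------------------------------------

def laf_sigmoid(x, p: LAFParams = LAFParams()):
    """a * logistic(W*x) + b, element-wise."""
    x = np.asarray(x, dtype=np.float64)
    s = stable_sigmoid(np.asarray(p.W) * x)
    return np.asarray(p.a) * s + np.asarray(p.b)


def laf_relu(x, p: LAFParams = LAFParams()):
    """a * max(0, W*x) + b, element-wise; subgradient at the kink is 0."""
    x = np.asarray(x, dtype=np.float64)
    return np.asarray(p.a) * np.maximum(0.0, np.asarray(p.W) * x) + np.asarray(p.b)


def laf_sigmoid_grads(x, p: LAFParams = LAFParams()):
    """Analytic partials of laf_sigmoid w.r.t. (x, a, b, W), element-wise."""
    x = np.asarray(x, dtype=np.float64)
    a, w = np.asarray(p.a, dtype=np.float64), np.asarray(p.W, dtype=np.float64)
    s = stable_sigmoid(w * x)
    ds = s * (1.0 - s)
    return {
        "x": a * ds * w,
        "a": s,
        "b": np.ones_like(s),
        "W": a * ds * x,
    }


def laf_relu_grads(x, p: LAFParams = LAFParams()):
    """Analytic partials of laf_relu w.r.t. (x, a, b, W), element-wise.

    The piecewise-linear kink at W*x = 0 carries subgradient 0.
    """
    x = np.asarray(x, dtype=np.float64)
    a, w = np.asarray(p.a, dtype=np.float64), np.asarray(p.W, dtype=np.float64)
    active = (w * x) > 0
    return {
        "x": a * w * active,
        "a": np.maximum(0.0, w * x),
        "b": np.ones_like(x) * np.ones_like(a * w),
        "W": a * x * active,
    }


# ---------------------------------------------------------------------------
# Trainable layers
# ---------------------------------------------------------------------------

class _LAFBase(Module):
    def __init__(self, channels: int, per_channel: bool = True):
        super().__init__()
        n = channels if per_channel else 1
        self.a = Tensor(np.ones(n), requires_grad=True)
        self.b = Tensor(np.zeros(n), requires_grad=True)
        self.W = Tensor(np.ones(n), requires_grad=True)

    def _bshape(self, x: Tensor) -> tuple:
        # feature maps are (N, C, H, W); dense activations are (N, C)
        return (1, -1, 1, 1) if x.data.ndim == 4 else (1, -1)

    def params_snapshot(self) -> LAFParams:
        """The current (a, b, W) values as a LAFParams record."""
        return LAFParams(a=self.a.data.copy(), b=self.b.data.copy(),
                         W=self.W.data.copy())

    def _fused_forward(self, x: Tensor, fa: np.ndarray,
                       dfa: np.ndarray) -> Tensor:
        """y = a*fa + b with a single backward closure.

        ``fa`` is F(W*x) and ``dfa`` is dF/d(pre) at pre = W*x, both already
        computed against the broadcast parameter shapes.
        """
        a, b, w = self.a, self.b, self.W
        bshape = self._bshape(x)
        ad = a.data.reshape(bshape)
        wd = w.data.reshape(bshape)
        out_data = ad * fa + b.data.reshape(bshape)
        if not _needs_grad(x, a, b, w):
            return Tensor(out_data)
        xd = x.data

        def backward(g):
            a._ensure_grad()
            a.grad += _unbroadcast(g * fa, ad.shape).reshape(a.data.shape)
            b._ensure_grad()
            b.grad += _unbroadcast(g, ad.shape).reshape(b.data.shape)
            w._ensure_grad()
            w.grad += _unbroadcast(g * ad * dfa * xd, ad.shape).reshape(w.data.shape)
            if x.requires_grad or x._parents or x._backward:
                x._ensure_grad()
                x.grad += (g * ad * dfa * wd).astype(DTYPE)

        return Tensor(out_data, parents=(x, a, b, w), backward=backward)


class LAFReLU(_LAFBase):
    """Trainable a * max(0, W*x) + b with one triple per channel."""

    def forward(self, x: Tensor) -> Tensor:
        wd = self.W.data.reshape(self._bshape(x))
        pre = wd * x.data
        mask = pre > 0
        fa = np.where(mask, pre, 0.0).astype(DTYPE)
        return self._fused_forward(x, fa, mask.astype(DTYPE))


class LAFSigmoid(_LAFBase):
    """Trainable a * logistic(W*x) + b with one triple per channel."""

    def forward(self, x: Tensor) -> Tensor:
        wd = self.W.data.reshape(self._bshape(x))
        s = stable_sigmoid((wd * x.data).astype(DTYPE))
        return self._fused_forward(x, s, (s * (1.0 - s)).astype(DTYPE))
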