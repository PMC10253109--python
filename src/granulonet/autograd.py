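"""Reverse-mode automatic differentiation on NumPy arrays.

This module is the numerical engine behind the network: a small tensor
graph with backward closures, the layer primitives the architecture needs
(im2col convolution, batch normalization, max pooling, spatial softmax,
dropout), a ``Module`` container with parameter/buffer registration, and
an Adam optimizer.  Everything runs in float32 on the CPU; convolutions
are lowered to a single GEMM per layer via an explicit k x k slice-gather
(im2col), and the col2im scatter in the backward pass is a k x k loop of
strided slice additions, so no per-element Python work happens on the
hot path.

Feature maps use the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Tensor and graph
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the computation graph: an ndarray plus an optional gradient.

    Gradients are accumulated into ``grad`` by the backward closures of the
    operations that consumed this tensor.  Only tensors created with
    ``requires_grad=True`` (parameters) or downstream of one participate in
    backpropagation.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def _ensure_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph eagerly: drop closures, edges and intermediate
        # gradients so each batch's memory is reclaimed before the next one
        for node in topo:
            node._backward = None
            node._parents = ()
            if not node.requires_grad:
                node.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents or t._backward is not None
               for t in ts)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise and shape ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    if not _needs_grad(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._parents or a._backward:
            a._ensure_grad()
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad or b._parents or b._backward:
            b._ensure_grad()
            b.grad += _unbroadcast(g, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data
    if not _needs_grad(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._parents or a._backward:
            a._ensure_grad()
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad or b._parents or b._backward:
            b._ensure_grad()
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.reshape(shape)
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        x._ensure_grad()
        x.grad += g.reshape(x.data.shape)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _needs_grad(*tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._ensure_grad()
            t.grad += g[tuple(sl)]

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        gg = g
        if not keepdims and axis is not None:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            for ax in sorted(axes):
                gg = np.expand_dims(gg, ax)
        x._ensure_grad()
        x.grad += np.broadcast_to(gg, x.data.shape)

    return Tensor(out_data, parents=(x,), backward=backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(x: Tensor) -> Tensor:
    """max(0, x); the subgradient at 0 is taken as 0."""
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0)
    if not _needs_grad(x):
        return Tensor(out_data)
    mask = x.data > 0

    def backward(g):
        x._ensure_grad()
        x.grad += g * mask

    return Tensor(out_data, parents=(x,), backward=backward)


def stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = stable_sigmoid(x.data)
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        x._ensure_grad()
        x.grad += g * out_data * (1.0 - out_data)

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x: Tensor, axis) -> Tensor:
    """Numerically stable softmax over ``axis`` (int or tuple of ints)."""
    x = as_tensor(x)
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    z = x.data - x.data.max(axis=axes, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axes, keepdims=True)
    if not _needs_grad(x):
        return Tensor(s)

    def backward(g):
        dot = (g * s).sum(axis=axes, keepdims=True)
        x._ensure_grad()
        x.grad += s * (g - dot)

    return Tensor(s, parents=(x,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (used by dense layers)."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data
    if not _needs_grad(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._parents or a._backward:
            a._ensure_grad()
            a.grad += g @ b.data.T
        if b.requires_grad or b._parents or b._backward:
            b._ensure_grad()
            b.grad += a.data.T @ g

    return Tensor(out_data, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# Spatial ops
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Gather k x k patches of a padded (N,C,H,W) array into (N, C*k*k, ho*wo)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
    return cols.reshape(n, c * k * k, ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, weight layout (C_out, C_in, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    co, ci, k, _ = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    p, s = padding, stride
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: spatial dims smaller than the filter")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    if k == 1 and s == 1:
        cols = xp.reshape(n, c, ho * wo)
    else:
        cols = _im2col(xp, k, s, ho, wo)
    wm = w.data.reshape(co, -1)
    y = np.matmul(wm, cols)  # (N, co, ho*wo)
    if b is not None:
        y += b.data.reshape(1, co, 1)
    out_data = y.reshape(n, co, ho, wo)
    parents = (x, w) if b is None else (x, w, b)
    if not _needs_grad(*parents):
        return Tensor(out_data)
    # large column matrices (k*k times the input size) are rebuilt from the
    # padded input during backward instead of being retained
    if not (k == 1 and s == 1) and cols.nbytes > 32 * 1024 * 1024:
        cols = None

    def backward(g):
        gy = g.reshape(n, co, ho * wo)
        local_cols = cols if cols is not None else _im2col(xp, k, s, ho, wo)
        if w.requires_grad or w._parents or w._backward:
            gw = np.tensordot(gy, local_cols, axes=([0, 2], [0, 2]))
            w._ensure_grad()
            w.grad += gw.reshape(w.data.shape)
        if b is not None and (b.requires_grad or b._parents or b._backward):
            b._ensure_grad()
            b.grad += gy.sum(axis=(0, 2))
        if x.requires_grad or x._parents or x._backward:
            dcols = np.matmul(wm.T, gy)  # (N, c*k*k, L)
            if k == 1 and s == 1:
                dx = dcols.reshape(n, c, h, wd)
                x._ensure_grad()
                x.grad += dx
            else:
                dc = dcols.reshape(n, c, k, k, ho, wo)
                dxp = np.zeros_like(xp)
                for ki in range(k):
                    for kj in range(k):
                        dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dc[:, :, ki, kj]
                x._ensure_grad()
                x.grad += dxp[:, :, p:p + h, p:p + wd] if p else dxp

    return Tensor(out_data, parents=parents, backward=backward)


def maxpool2d(x: Tensor, k: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling; padding uses -inf so padded positions never win.

    On ties (e.g. constant regions) the gradient is routed to every maximal
    position in the window, a valid subgradient choice.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    p, s = padding, stride
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if p:
        xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=x.data.dtype)
        xp[:, :, p:p + h, p:p + w] = x.data
    else:
        xp = x.data
    out_data = np.full((n, c, ho, wo), -np.inf, dtype=x.data.dtype)
    for ki in range(k):
        for kj in range(k):
            np.maximum(out_data, xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s],
                       out=out_data)
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                sl = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += g * (sl == out_data)
        x._ensure_grad()
        x.grad += dxp[:, :, p:p + h, p:p + w] if p else dxp

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return tmean(x, axis=(2, 3))


def upsample_nearest(x: Tensor, factor: int, out_hw: tuple[int, int] | None = None) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor, cropped to out_hw."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    y = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    if out_hw is not None:
        y = y[:, :, :out_hw[0], :out_hw[1]]
    oh, ow = y.shape[2:]
    if not _needs_grad(x):
        return Tensor(y)

    def backward(g):
        gx = np.zeros_like(x.data)
        for i in range(factor):
            for j in range(factor):
                blk = g[:, :, i::factor, j::factor]
                gx[:, :, :blk.shape[2], :blk.shape[3]] += blk
        x._ensure_grad()
        x.grad += gx

    return Tensor(y, parents=(x,), backward=backward)


def cross_entropy_from_probs(probs: Tensor, labels: np.ndarray,
                             eps: float = 1e-12) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``probs``.

    ``probs`` is an (N, K) tensor of class probabilities (already softmaxed);
    the gradient flows through the selected entries only.
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=np.int64)
    n = probs.data.shape[0]
    idx = np.arange(n)
    picked = np.clip(probs.data[idx, labels], eps, None)
    out_data = np.array(-np.log(picked).mean(), dtype=DTYPE)
    if not _needs_grad(probs):
        return Tensor(out_data)

    def backward(g):
        probs._ensure_grad()
        gp = np.zeros_like(probs.data)
        gp[idx, labels] = -float(g) / (n * picked)
        probs.grad += gp

    return Tensor(out_data, parents=(probs,), backward=backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class with automatic parameter/child registration.

    Assigning a ``Tensor`` with ``requires_grad=True`` registers a parameter;
    assigning a ``Module`` (or ``ModuleList``) registers a child.  Buffers
    (non-trained state such as batch-norm running moments) are registered
    explicitly and travel with the state dict.
    """

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value, dtype=DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data
        for k, v in self._buffers.items():
            out[prefix + k] = v
        for name, child in self._children.items():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, v in self._params.items():
            v.data[...] = state[prefix + k]
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
            object.__setattr__(self, k, self._buffers[k])
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList:
    """An ordered container of child modules."""

    def __init__(self, modules: Iterable[Module] = ()):
        self._list = list(modules)

    def append(self, m: Module):
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)

    def parameters(self):
        out = []
        for m in self._list:
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        for m in self._list:
            m.train(mode)
        return self

    def state_dict(self, prefix: str = ""):
        out = {}
        for i, m in enumerate(self._list):
            out.update(m.state_dict(f"{prefix}{i}."))
        return out

    def load_state_dict(self, state, prefix: str = ""):
        for i, m in enumerate(self._list):
            m.load_state_dict(state, f"{prefix}{i}.")


class Conv2d(Module):
    """Convolution layer with He-normal init and 'same' padding for odd k."""

    def __init__(self, in_channels: int, out_channels: int, k: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.stride = stride
        self.padding = k // 2
        self.weight = Tensor(rng.normal(0.0, std, (out_channels, in_channels, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        lim = float(np.sqrt(6.0 / (in_features + out_features)))
        self.weight = Tensor(rng.uniform(-lim, lim, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes with batch moments and updates running
    estimates; eval mode is a fixed affine map using the running moments,
    which keeps inference deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu
            # unbiased variance for the running estimate
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var * (m / max(m - 1, 1))
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
            out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

            def backward(g):
                gsum = g.sum(axis=(0, 2, 3))
                gxhat_sum = (g * xhat).sum(axis=(0, 2, 3))
                if gamma.requires_grad:
                    gamma._ensure_grad()
                    gamma.grad += gxhat_sum
                if beta.requires_grad:
                    beta._ensure_grad()
                    beta.grad += gsum
                if x.requires_grad or x._parents or x._backward:
                    coeff = (gamma.data * inv / m).reshape(1, c, 1, 1)
                    dx = coeff * (m * g
                                  - gsum.reshape(1, c, 1, 1)
                                  - xhat * gxhat_sum.reshape(1, c, 1, 1))
                    x._ensure_grad()
                    x.grad += dx.astype(DTYPE)

            return Tensor(out_data, parents=(x, gamma, beta), backward=backward)
        # eval: fixed affine transform
        scale = (gamma.data / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        shift = (beta.data - gamma.data * self.running_mean
                 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        out_data = x.data * scale + shift
        if not _needs_grad(x, gamma, beta):
            return Tensor(out_data)

        def backward_eval(g):
            if x.requires_grad or x._parents or x._backward:
                x._ensure_grad()
                x.grad += g * scale
            # parameter grads in eval mode are rarely needed; computed anyway
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x.data - self.running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
            gamma._ensure_grad()
            gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
            beta._ensure_grad()
            beta.grad += g.sum(axis=(0, 2, 3))

        return Tensor(out_data, parents=(x, gamma, beta), backward=backward_eval)


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    The mask stream comes from the module's own Generator so a fixed
    construction seed plus an identical call sequence is bit-reproducible.
    """

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(DTYPE) / keep
        return mul(x, Tensor(mask))


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
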