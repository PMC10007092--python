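"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine providing exactly the operations the
wavelet attention network needs: broadcast arithmetic, matmul, same-padded 2D
convolution (via im2col + BLAS matmul), global and channel-wise pooling,
sigmoid / leaky-ReLU / softmax nonlinearities, channel concatenation, 2x
bilinear upsampling and an orthonormal inverse wavelet layer. All math is in
double precision; gradients are accumulated by a topological backward sweep.

Feature maps follow the (height, width, channels) field convention; kernels
are (kh, kw, in_channels, out_channels).
"""
from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "conv2d", "upsample2x"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._bw: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _child(data, parents: tuple["Tensor", ...], bw) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._bw = bw
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bw is not None:
                node._bw(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        o = _wrap(other)
        out = Tensor._child(self.data + o.data, (self, o), None)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            o._accum(_unbroadcast(g, o.data.shape))

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._child(-self.data, (self,), None)
        out._bw = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        o = _wrap(other)
        out = Tensor._child(self.data * o.data, (self, o), None)

        def bw(g):
            self._accum(_unbroadcast(g * o.data, self.data.shape))
            o._accum(_unbroadcast(g * self.data, o.data.shape))

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _wrap(other)
        out = Tensor._child(self.data / o.data, (self, o), None)

        def bw(g):
            self._accum(_unbroadcast(g / o.data, self.data.shape))
            o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))

        out._bw = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor._child(self.data ** p, (self,), None)
        out._bw = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        o = _wrap(other)
        out = Tensor._child(self.data @ o.data, (self, o), None)

        def bw(g):
            a, b = self.data, o.data
            if a.ndim == 1 and b.ndim == 2:       # (k,) @ (k,n) -> (n,)
                self._accum(g @ b.T)
                o._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 2:     # (m,k) @ (k,n)
                self._accum(g @ b.T)
                o._accum(a.T @ g)
            else:
                raise NotImplementedError("matmul backward for ndim > 2")

        out._bw = bw
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(np.float64))
                return
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            if not keepdims:
                for ax in sorted(a % len(shape) for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape).astype(np.float64))

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._child(y, (self,), None)
        out._bw = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        mask = np.where(self.data >= 0, 1.0, alpha)
        out = Tensor._child(self.data * mask, (self,), None)
        out._bw = lambda g: self._accum(g * mask)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._child(p, (self,), None)

        def bw(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        out._bw = bw
        return out

    # -- pooling (feature maps are (H, W, C)) ---------------------------------

    def spatial_max(self):
        """Global max over spatial axes -> (C,). Ties go to the first index."""
        h, w, c = self.data.shape
        flat = self.data.reshape(-1, c)
        idx = flat.argmax(axis=0)
        out = Tensor._child(flat[idx, np.arange(c)], (self,), None)

        def bw(g):
            gf = np.zeros_like(flat)
            gf[idx, np.arange(c)] = g
            self._accum(gf.reshape(h, w, c))

        out._bw = bw
        return out

    def spatial_mean(self):
        """Global average over spatial axes -> (C,)."""
        return self.mean(axis=(0, 1))

    def channel_max(self):
        """Max over channel axis -> (H, W, 1)."""
        h, w, c = self.data.shape
        idx = self.data.argmax(axis=2)
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        out = Tensor._child(self.data[ii, jj, idx][..., None], (self,), None)

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[ii, jj, idx] = g[..., 0]
            self._accum(gx)

        out._bw = bw
        return out

    def channel_mean(self):
        """Mean over channel axis -> (H, W, 1)."""
        return self.mean(axis=2, keepdims=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g to `shape` by summing broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- structural ops ---------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 2) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out = Tensor._child(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), None)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._bw = bw
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 correlation: (H,W,Cin) * (kh,kw,Cin,Cout) -> (H,W,Cout).

    Odd kernel sizes only (1/3/5/7 in this package). Implemented as im2col
    plus a BLAS matmul; the input gradient is the full correlation with the
    spatially flipped, channel-transposed kernel.
    """
    x, weight = _wrap(x), _wrap(weight)
    kh, kw, cin, cout = weight.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    h, w, cx = x.data.shape
    if cx != cin:
        raise ValueError(f"input has {cx} channels, kernel expects {cin}")
    ph, pw = kh // 2, kw // 2
    cols = _im2col(x.data, kh, kw)                       # (H*W, kh*kw*Cin)
    wmat = weight.data.transpose(0, 1, 2, 3).reshape(kh * kw * cin, cout)
    y = (cols @ wmat).reshape(h, w, cout)
    if bias is not None:
        bias = _wrap(bias)
        y = y + bias.data
        parents = (x, weight, bias)
    else:
        parents = (x, weight)
    out = Tensor._child(y, parents, None)

    def bw(g):
        gflat = g.reshape(-1, cout)
        weight._accum((cols.T @ gflat).reshape(kh, kw, cin, cout))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 1)))
        # dX: correlate g with flipped kernel, swapping in/out channels
        wflip = weight.data[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * cout, cin)
        gcols = _im2col(g, kh, kw)
        x._accum((gcols @ wflip).reshape(h, w, cin))

    out._bw = bw
    return out


def _im2col(arr: np.ndarray, kh: int, kw: int) -> np.ndarray:
    h, w, c = arr.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(arr, ((ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(0, 1))
    # win: (H, W, C, kh, kw) -> (H*W, kh*kw*C) matching weight.reshape order
    return win.transpose(0, 1, 3, 4, 2).reshape(h * w, kh * kw * c)


def _lin_idx(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-pixel bilinear source indices/weights for 2x upsampling."""
    s = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(s).astype(int), 0, n - 1)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = np.clip(s - np.floor(s), 0.0, 1.0)
    frac[s < 0] = 0.0
    return i0, i1, frac


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of an (H, W, C) map (half-pixel centers)."""
    x = _wrap(x)
    h, w, c = x.data.shape
    r0, r1, rf = _lin_idx(h)
    c0, c1, cf = _lin_idx(w)
    rows = x.data[r0] * (1 - rf)[:, None, None] + x.data[r1] * rf[:, None, None]
    y = rows[:, c0] * (1 - cf)[None, :, None] + rows[:, c1] * cf[None, :, None]
    out = Tensor._child(y, (x,), None)

    def bw(g):
        grows = np.zeros((2 * h, w, c))
        gt = grows.transpose(1, 0, 2)
        np.add.at(gt, c0, (g * (1 - cf)[None, :, None]).transpose(1, 0, 2))
        np.add.at(gt, c1, (g * cf[None, :, None]).transpose(1, 0, 2))
        gx = np.zeros_like(x.data)
        np.add.at(gx, r0, grows * (1 - rf)[:, None, None])
        np.add.at(gx, r1, grows * rf[:, None, None])
        x._accum(gx)

    out._bw = bw
    return out


class Adam:
    """Adam optimizer over a name->Tensor parameter mapping (deterministic order)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(sorted(params.items()))
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * p.grad
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
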