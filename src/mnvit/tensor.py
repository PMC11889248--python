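"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ``ndarray`` together with an optional
gradient and a closure that propagates gradients to its parents.  The op set
is exactly what the micronucleus classifier needs: broadcasting arithmetic,
(batched) matmul, dense and depthwise 2-D convolution, reductions, shape
manipulation, the sigmoid/SiLU/softmax nonlinearities and a numerically
stable cross-entropy.  ``backward`` runs a topological sort over the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "depthwise_conv2d", "softmax", "cross_entropy", "concat"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                if b.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s

        def bwd(g):
            a._accumulate(g * (s + a.data * s * (1.0 - s)))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)


# -- free functions -------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (N, K)."""
    n, k = logits.shape
    m = logits.data.max(axis=1, keepdims=True)
    shifted = logits - Tensor(m)
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    logprobs = shifted - logsumexp
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(logprobs * Tensor(onehot)).sum() * (1.0 / n)


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D cross-correlation, NCHW input, (C_out, C_in, k, k) weight."""
    xn, wn = x.data, w.data
    n, cin, h, wid = xn.shape
    cout, cin2, kh, kw = wn.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin2}")
    xp = _pad_hw(xn, padding)
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    out = (cols @ wn.reshape(cout, -1).T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            gw = gmat.T @ cols
            w._accumulate(gw.reshape(cout, cin, kh, kw))
        if x.requires_grad:
            gcols = (gmat @ wn.reshape(cout, -1)).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u : u + ho * stride : stride, v : v + wo * stride : stride] += (
                        gcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
                    )
            gx = gxp[:, :, padding : padding + h, padding : padding + wid] if padding else gxp
            x._accumulate(gx)

    return Tensor._make(np.ascontiguousarray(out), (x, w), bwd)


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 2-D cross-correlation; weight shape (C, k, k)."""
    xn, wn = x.data, w.data
    n, c, h, wid = xn.shape
    c2, kh, kw = wn.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
    xp = _pad_hw(xn, padding)
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    out = np.einsum("nchwuv,cuv->nchw", win, wn, optimize=True)

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nchwuv->cuv", g, win, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u : u + ho * stride : stride, v : v + wo * stride : stride] += (
                        g * wn[None, :, u, v, None, None]
                    )
            gx = gxp[:, :, padding : padding + h, padding : padding + wid] if padding else gxp
            x._accumulate(gx)

    return Tensor._make(np.ascontiguousarray(out), (x, w), bwd)
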