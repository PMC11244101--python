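"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the fusion network: broadcast-aware arithmetic,
matmul (batched), 2-D convolution via im2col/BLAS, reductions, softmax and
cross-entropy.  float32 throughout; gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "softmax", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, prev: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("tensor does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long conv stacks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basics ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))
        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))
        return Tensor._make(out_data, (self, other), bwd)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))
        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def amax(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg, oo = g, out_data
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
                oo = np.expand_dims(oo, axis)
            mask = (self.data == oo).astype(np.float32)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            self._accum(mask * gg)
        return Tensor._make(out_data, (self,), bwd)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            self._accum(g * (self.data > 0))
        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor._make(out_data, (self,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])
    return Tensor._make(out_data, tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)  # shift for stability
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
    return Tensor._make(s, (x,), bwd)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under row softmax."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)
    return Tensor._make(np.float32(loss), (logits,), bwd)


# ---------------------------------------------------------------------------
# 2-D convolution (im2col + BLAS matmul forward; slice-accumulate backward)

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: tuple[int, int] = (1, 1),
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """x: [N, C, H, W]; w: [O, C, kh, kw]; 'same'-style padding via ``padding``."""
    sh, sw = stride
    ph, pw = padding
    nb, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                              # [N,C,ho,wo,kh,kw]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(nb * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data.reshape(1, o)
    out = out.reshape(nb, ho, wo, o).transpose(0, 3, 1, 2)

    def bwd(g):
        gr = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(nb * ho * wo, o)
        if w.requires_grad:
            w._accum((gr.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gr.sum(axis=0).reshape(b.data.shape))
        if x.requires_grad:
            dcols = (gr @ wmat).reshape(nb, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((nb, c, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * sh:sh, j:j + wo * sw:sw] += dcols[:, :, :, :, i, j]
            x._accum(dxp[:, :, ph:ph + h, pw:pw + wd] if (ph or pw) else dxp)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, prev, bwd)
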