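"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the segmentation network: dense tensors,
a handful of differentiable primitives (matmul, layer norm, softmax, GELU,
bilinear resampling expressed as two interpolation matrices, cross-entropy),
and an Adam optimizer.  Only what the encoder/decoder architecture needs is
implemented; gradients are verified against central differences in the test
suite.

Gradient flow vs. trainability are distinct: a frozen parameter
(``requires_grad=False``) never accumulates ``.grad`` but gradients still
propagate *through* operations that use it, which is exactly the LoRA
fine-tuning regime (frozen base weights, trainable low-rank adapters).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen and child.requires_grad:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _result(data, parents: tuple["Tensor", ...]) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad))
        return out

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = self._result(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._result(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        out = self._result(self.data ** exponent, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g * exponent * self.data ** (exponent - 1))
            out._backward = _bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = self._result(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g.reshape(self.shape))
            out._backward = _bw
        return out

    def transpose(self, *axes):
        out = self._result(self.data.transpose(*axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            def _bw(g):
                self._accumulate(g.transpose(*inv))
            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = self._result(self.data[idx], (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _bw
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        datas = [t.data for t in tensors]
        out = Tensor._result(np.concatenate(datas, axis=axis), tuple(tensors))
        if out.requires_grad:
            sizes = [d.shape[axis] for d in datas]
            offsets = np.cumsum([0] + sizes)
            def _bw(g):
                for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                    if t.requires_grad:
                        sl = [slice(None)] * g.ndim
                        sl[axis] = slice(lo, hi)
                        t._accumulate(g[tuple(sl)])
            out._backward = _bw
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        e = np.exp(self.data)
        out = self._result(e, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g * e)
            out._backward = _bw
        return out

    def log(self):
        out = self._result(np.log(self.data), (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g / self.data)
            out._backward = _bw
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        from scipy.special import erf
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = self._result(x * cdf, (self,))
        if out.requires_grad:
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            def _bw(g):
                self._accumulate(g * (cdf + x * pdf))
            out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._result(s, (self,))
        if out.requires_grad:
            def _bw(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))
            out._backward = _bw
        return out

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other: "Tensor"):
        other = self._wrap(other)
        out = self._result(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = _bw
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-6):
        """Layer normalization over the last axis."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = self._result(xhat * gamma.data + beta.data, (self, gamma, beta))
        if out.requires_grad:
            d = x.shape[-1]
            def _bw(g):
                if gamma.requires_grad:
                    gamma._accumulate(
                        (g * xhat).sum(axis=tuple(range(g.ndim - 1))))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
                if self.requires_grad:
                    gx = g * gamma.data
                    term1 = gx
                    term2 = gx.mean(axis=-1, keepdims=True)
                    term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                    self._accumulate(inv * (term1 - term2 - term3))
            out._backward = _bw
        return out

    def interp2d(self, w_row: np.ndarray, w_col: np.ndarray):
        """Linear spatial resampling of a (B, H, W, C) tensor.

        ``w_row`` has shape (H_out, H) and ``w_col`` (W_out, W); the output is
        y[b,i,j,c] = sum_{h,w} w_row[i,h] * w_col[j,w] * x[b,h,w,c].
        The interpolation matrices are constants (no gradient).
        """
        y = np.einsum("ih,jw,bhwc->bijc", w_row, w_col, self.data, optimize=True)
        out = self._result(y, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(
                    np.einsum("ih,jw,bijc->bhwc", w_row, w_col, g, optimize=True))
            out._backward = _bw
        return out

    def cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy of (N, C) logits against integer labels (N,)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        n = self.data.shape[0]
        nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300))
        out = self._result(nll.mean(), (self,))
        if out.requires_grad:
            def _bw(g):
                gp = p.copy()
                gp[np.arange(n), labels] -= 1.0
                self._accumulate(g * gp / n)
            out._backward = _bw
        return out


class Parameter(Tensor):
    """A trainable (or deliberately frozen) leaf tensor."""

    def __init__(self, data, requires_grad: bool = True):
        super().__init__(data, requires_grad=requires_grad)


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
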