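"""Reverse-mode automatic differentiation over numpy arrays.

A compact define-by-run autodiff core: each operation records its parents
and a closure that accumulates gradients into them.  Arrays are float32
throughout; image tensors use NHWC layout.  The op set is exactly what the
segmentation and classification networks need (dense/conv/pool/resize
algebra plus the usual pointwise nonlinearities and reductions).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "max_pool2x2", "upsample_nearest2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, expo: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * expo * self.data ** (expo - 1.0))

        return Tensor._make(self.data ** expo, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- pointwise ------------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.where(mask, self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / reshaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(np.float32))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def _same_pad(size: int, stride: int, k_eff: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k_eff - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, stride: int = 1, dilation: int = 1,
           padding: str = "same") -> Tensor:
    """2-D correlation of NHWC input `x` with filter bank `w` (kh, kw, Cin, Cout).

    Implemented as kh*kw shifted matrix products, which keeps both the forward
    and the backward pass inside BLAS.
    """
    N, H, W, Cin = x.shape
    kh, kw, wcin, Cout = w.shape
    if wcin != Cin:
        raise ValueError(f"filter expects {wcin} input channels, got {Cin}")
    keh = (kh - 1) * dilation + 1
    kew = (kw - 1) * dilation + 1
    if padding == "same":
        ph = _same_pad(H, stride, keh)
        pw = _same_pad(W, stride, kew)
    elif padding == "valid":
        ph = pw = (0, 0)
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = x.data
    padded = ph != (0, 0) or pw != (0, 0)
    if padded:
        xp = np.pad(xp, ((0, 0), ph, pw, (0, 0)))
    Hp, Wp = xp.shape[1:3]
    Ho = (Hp - keh) // stride + 1
    Wo = (Wp - kew) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("filter larger than (padded) input")

    slices = []
    out_flat = np.zeros((N * Ho * Wo, Cout), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            r0, c0 = i * dilation, j * dilation
            sl = (
                slice(None),
                slice(r0, r0 + (Ho - 1) * stride + 1, stride),
                slice(c0, c0 + (Wo - 1) * stride + 1, stride),
                slice(None),
            )
            slices.append(sl)
            out_flat += xp[sl].reshape(-1, Cin) @ w.data[i, j]
    out_data = out_flat.reshape(N, Ho, Wo, Cout)

    def backward(g):
        gf = g.reshape(-1, Cout)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for idx, sl in enumerate(slices):
                i, j = divmod(idx, kw)
                gw[i, j] = xp[sl].reshape(-1, Cin).T @ gf
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for idx, sl in enumerate(slices):
                i, j = divmod(idx, kw)
                gxp[sl] += (gf @ w.data[i, j].T).reshape(N, Ho, Wo, Cin)
            if padded:
                gxp = gxp[:, ph[0]:Hp - ph[1] or None, pw[0]:Wp - pw[1] or None, :]
            x._accum(gxp)

    return Tensor._make(out_data, (x, w), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    N, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    H2, W2 = H // 2, W // 2
    windows = (
        x.data.reshape(N, H2, 2, W2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N, H2, W2, 4, C)
    )
    arg = windows.argmax(axis=3)
    out_data = np.take_along_axis(windows, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros((N, H2, W2, 4, C), dtype=np.float32)
        np.put_along_axis(gw, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gx = (
            gw.reshape(N, H2, W2, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(N, H, W, C)
        )
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    N, H, W, C = x.shape
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)))

    return Tensor._make(out_data, (x,), backward)
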