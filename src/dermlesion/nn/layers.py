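"""Layer primitives: parameters, modules, conv/dense/batch-norm."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            if isinstance(obj, Parameter):
                params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(vars(obj).values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            if isinstance(obj, Module):
                mods.append(obj)
                stack.extend(vars(obj).values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
        return mods

    def train(self) -> None:
        for m in self.modules():
            m._training = True

    def eval(self) -> None:
        for m in self.modules():
            m._training = False

    _training = True

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and buffer arrays, in deterministic traversal order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            p.data = np.asarray(next(it), dtype=np.float32).reshape(p.data.shape)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = np.asarray(next(it), dtype=np.float32)
                m.running_var = np.asarray(next(it), dtype=np.float32)


class Conv2D(Module):
    """3x3 (or kxk) same/valid convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 dilation: int = 1, padding: str = "same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.standard_normal((k, k, cin, cout)) * std)
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, stride=self.stride, dilation=self.dilation,
                     padding=self.padding)
        if self.bias is not None:
            out = out + self.bias
        return out


class Dense(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / din)
        self.weight = Parameter(rng.standard_normal((din, dout)) * std)
        self.bias = Parameter(np.zeros(dout))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalisation over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self._training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xn = (x - mu) * (var + self.eps) ** -0.5
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta
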