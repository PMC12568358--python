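"""Small neural-network layer library on top of :mod:`udrnet._autodiff`.

Layers hold their parameters as ``Tensor``s with ``requires_grad=True`` and
register them on a flat, ordered dict so weights can be counted, serialized
to ``.npz`` and restored by name.  Initialization is He-uniform (fan-in)
driven by an explicit ``numpy.random.Generator`` so model construction is
fully reproducible from a seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ._autodiff import Tensor, conv3d, conv_transpose3d, matmul


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict is missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {name!r}: stored shape {arr.shape} != model "
                    f"shape {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv3d(Module):
    """Stride-1, shape-preserving 3D convolution (odd kernel, pad = k // 2)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("Conv3d supports odd kernels only")
        self.pad = kernel // 2
        shape = (c_out, c_in, kernel, kernel, kernel)
        fan_in = c_in * kernel ** 3
        w = np.zeros(shape, np.float32) if zero_init else _he_uniform(rng, shape, fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, pad=self.pad)


class ConvTranspose3d(Module):
    """Kernel-3 stride-2 transposed convolution: doubles spatial dims."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        shape = (c_in, c_out, 3, 3, 3)
        self.weight = Tensor(_he_uniform(rng, shape, c_in * 27), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_uniform(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
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

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
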