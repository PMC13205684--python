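"""Layer primitives and modules built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, upsample1d


class Module:
    """Base class: tracks parameters, supports freezing and state export."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
            p.grad = None
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = True
        return self

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        if padding is None:
            padding = k // 2
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = Tensor(rng.normal(0, scale, (c_out, c_in, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ResBlock1d(Module):
    """Two same-length convolutions with a skip connection.

    The second convolution starts near zero so each block begins close
    to the identity, keeping activation variance stable with depth.
    """

    def __init__(self, channels: int, k: int, rng: np.random.Generator):
        self.c1 = Conv1d(channels, channels, k, rng)
        self.c2 = Conv1d(channels, channels, k, rng)
        self.c2.w.data *= 0.1

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h)
        return (x + h).relu()


class Upsample1d(Module):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample1d(x, self.factor)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Relu(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
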