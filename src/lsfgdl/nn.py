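"""Neural-network building blocks on top of the autodiff engine.

Contains parameter containers, affine layers, the SiLU multilayer perceptron
used throughout the borylation networks, and the Adam optimizer with the
step-decay learning-rate schedule used for training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "MLP", "Adam"]


class Module:
    """Base class with recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch while loading state")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


class Linear(Module):
    """Affine map with Glorot-uniform weights and zero bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Feed-forward block: Linear (+ SiLU) stacks given explicit layer dims.

    `dims` lists all layer widths including input and output; SiLU is applied
    between layers and optionally after the last one.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator, activate_last: bool = False):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activate_last = activate_last

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < last or self.activate_last:
                x = x.silu()
        return x


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999) with optional LR step decay."""

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
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
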