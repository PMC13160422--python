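"""Neural-network building blocks over :mod:`mtmolgen.autodiff`.

Layers hold their parameters in an ordered dict so a model can expose a flat
name -> Tensor mapping for the optimizer and for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, t in val.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, (n, d)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        from .autodiff import embedding
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import layer_normalize
        return layer_normalize(x, self.eps) * self.gain + self.shift


class FeedForward(Module):
    """Position-wise 2-layer MLP with tanh nonlinearity."""

    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


class Adam:
    """Adam optimizer over a flat name -> Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
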