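"""Basic neural-network building blocks on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "Dropout", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Minimal module: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def register_buffer(self, key: str, value: np.ndarray):
        self._buffers[key] = value
        object.__setattr__(self, key, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        for k, v in self._buffers.items():
            out[prefix + k] = v
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            p.data = np.array(state[prefix + k], dtype=np.float64)
        for k in list(self._buffers):
            arr = np.array(state[prefix + k], dtype=np.float64)
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = np.zeros((in_dim, out_dim)) if zero_init else glorot(rng, in_dim, out_dim)
        self.weight = Tensor(w, requires_grad=True, name="weight")
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True, name="bias")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True, name="gamma")
        self.beta = Tensor(np.zeros(dim), requires_grad=True, name="beta")
        self.register_buffer("running_mean", np.zeros(dim))
        self.register_buffer("running_var", np.ones(dim))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered * ((var + self.eps) ** -0.5)
            m = self.momentum
            new_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            new_var = (1 - m) * self.running_var + m * var.data.ravel()
            self.register_buffer("running_mean", new_mean)
            self.register_buffer("running_var", new_var)
        else:
            xhat = (x - self.running_mean) * (
                (self.running_var + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
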