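"""Layers composed from the autodiff primitives.

Parameters are float32.  Every layer exposes ``parameters()`` (trainable
tensors) and ``state_dict()``/``load_state_dict`` for checkpointing; layers
with train/eval behaviour (batch norm) honour a ``training`` flag set through
``Module.train()`` / ``Module.eval()``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self):
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def train(self):
        self.training = True
        for _, m in self._modules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for _, m in self._modules():
            m.eval()
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor):
                state[prefix + name] = v.data.copy()
            elif isinstance(v, np.ndarray):
                state[prefix + name] = v.copy()
        for name, m in self._modules():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in list(self.__dict__.items()):
            key = prefix + name
            if isinstance(v, Tensor) and key in state:
                v.data = state[key].astype(v.data.dtype, copy=True)
            elif isinstance(v, np.ndarray) and key in state:
                self.__dict__[name] = state[key].copy()
        for name, m in self._modules():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(1.0 / fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(np.float32),
                  requires_grad=True)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _param(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Causal dilated 1-D convolution layer: (N, L, C) -> (N, L, F)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        super().__init__()
        self.dilation = dilation
        self.w = _param(rng, (kernel, c_in, c_out), c_in * kernel)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d_causal(x, self.w, self.b, dilation=self.dilation)


class BatchNorm1d(Module):
    """Batch normalisation over the sample axis of (N, F) inputs."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(n_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class TCNBlock(Module):
    """Residual block of two causal dilated convolutions with ReLU.

    Follows the standard temporal-convolutional-network design: the skip path
    is a 1x1 convolution when channel counts differ, identity otherwise.  No
    normalisation inside the block — keeps each output step a function of past
    input steps only, independent of the rest of the batch.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(c_in, c_out, kernel, rng, dilation=dilation)
        self.conv2 = Conv1d(c_out, c_out, kernel, rng, dilation=dilation)
        self.skip = Conv1d(c_in, c_out, 1, rng) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(ad.relu(self.conv1(x)))
        s = self.skip(x) if self.skip is not None else x
        return ad.relu(y + s)


class TCNStack(Module):
    """One residual block per dilation rate, all with the same filter count."""

    def __init__(self, c_in: int, n_filters: int, kernel: int,
                 dilations: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        blocks = []
        c = c_in
        for d in dilations:
            blocks.append(TCNBlock(c, n_filters, kernel, d, rng))
            c = n_filters
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class LSTM(Module):
    """Single-layer LSTM over (N, T, F) inputs; returns the last hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_hidden = n_hidden
        self.wx = _param(rng, (n_in, 4 * n_hidden), n_in)
        self.wh = _param(rng, (n_hidden, 4 * n_hidden), n_hidden)
        b = np.zeros(4 * n_hidden, dtype=np.float32)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias: standard stabiliser
        self.b = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.lstm_last_hidden(x, self.wx, self.wh, self.b)
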