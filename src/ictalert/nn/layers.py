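"""Neural-network layers used by the seizure prediction models.

All layers follow the ``(batch, channels, time)`` array convention.
Parameters are held as :class:`Param` objects so that optimisers can skip
frozen tensors and so that whole models can be serialised to flat
name -> array dictionaries (see :meth:`Layer.state_dict`).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, concat, conv1d, lstm_last, swish, upsample1d

__all__ = [
    "Param",
    "Layer",
    "Conv1D",
    "BatchNorm1D",
    "SpatialDropout1D",
    "UpSample1D",
    "Dense",
    "BiLSTM",
    "Swish",
    "Sequential",
]


class Param:
    """A named, optionally trainable parameter tensor."""

    def __init__(self, data: np.ndarray, name: str, trainable: bool = True):
        self.tensor = Tensor(np.asarray(data, dtype=np.float32), requires_grad=trainable)
        self.name = name
        self._trainable = trainable

    @property
    def data(self) -> np.ndarray:
        return self.tensor.data

    @data.setter
    def data(self, value: np.ndarray) -> None:
        self.tensor.data = np.asarray(value, dtype=self.tensor.data.dtype)

    @property
    def trainable(self) -> bool:
        return self._trainable

    @trainable.setter
    def trainable(self, value: bool) -> None:
        self._trainable = bool(value)
        self.tensor.requires_grad = self._trainable


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class: parameter iteration, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self) -> Iterator[Param]:
        for attr in vars(self).values():
            if isinstance(attr, Param):
                yield attr
            elif isinstance(attr, Layer):
                yield from attr.params()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Layer):
                        yield from item.params()
                    elif isinstance(item, Param):
                        yield item

    def sublayers(self) -> Iterator["Layer"]:
        for attr in vars(self).values():
            if isinstance(attr, Layer):
                yield attr
                yield from attr.sublayers()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Layer):
                        yield item
                        yield from item.sublayers()

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for layer in self.sublayers():
            layer.training = mode

    def set_trainable(self, flag: bool) -> None:
        for p in self.params():
            p.trainable = flag

    # buffers (non-trainable state such as batch-norm running stats)
    def buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.params()}
        for layer in [self, *self.sublayers()]:
            for name, buf in layer.buffers():
                state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {p.name: p for p in self.params()}
        buf_owners: dict[str, tuple[Layer, str]] = {}
        for layer in [self, *self.sublayers()]:
            for name, _ in layer.buffers():
                buf_owners[name] = (layer, name)
        missing = (set(own) | set(buf_owners)) - set(state)
        extra = set(state) - (set(own) | set(buf_owners))
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {own[name].data.shape} vs {arr.shape}"
                    )
                own[name].data = arr.copy()
            else:
                layer, bname = buf_owners[name]
                layer._set_buffer(bname, arr.copy())


class Conv1D(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        name: str = "conv",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel
        self.w = Param(
            glorot_uniform(rng, (out_channels, in_channels, kernel), fan_in, out_channels * kernel),
            f"{name}.w",
        )
        self.b = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.b")

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w.tensor, self.b.tensor, stride=self.stride, pad=self.pad)


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, time).

    In training mode statistics come from the batch and running statistics
    are updated; in eval mode the running statistics are used, so a frozen
    encoder behaves as a fixed deterministic feature extractor.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self._name = name
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def buffers(self):
        yield f"{self._name}.running_mean", self.running_mean
        yield f"{self._name}.running_var", self.running_var

    def _set_buffer(self, name: str, arr: np.ndarray) -> None:
        if name.endswith("running_mean"):
            self.running_mean = arr
        else:
            self.running_var = arr

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        axes = (0, 2) if x.ndim == 3 else (0,)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean
                + (1 - self.momentum) * mu.data.reshape(-1).astype(np.float32)
            )
            self.running_var = (
                self.momentum * self.running_var
                + (1 - self.momentum) * var.data.reshape(-1).astype(np.float32)
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        g = self.gamma.tensor.reshape(*shape)
        b = self.beta.tensor.reshape(*shape)
        return xhat * g + b


class SpatialDropout1D(Layer):
    """Drops whole channels at training time (inverted dropout)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=(x.shape[0], x.shape[1], 1))
        return x * (mask.astype(x.data.dtype) / keep)


class UpSample1D(Layer):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample1d(x, self.factor)


class Swish(Layer):
    def forward(self, x: Tensor) -> Tensor:
        return swish(x)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, name: str = "dense", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = Param(glorot_uniform(rng, (in_features, out_features), in_features, out_features), f"{name}.w")
        self.b = Param(np.zeros(out_features, dtype=np.float32), f"{name}.b")

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w.tensor + self.b.tensor


class _LSTMDirection(Layer):
    def __init__(self, input_size: int, hidden: int, name: str, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Param(
            glorot_uniform(rng, (input_size, 4 * hidden), input_size, 4 * hidden), f"{name}.wx"
        )
        self.wh = Param(
            glorot_uniform(rng, (hidden, 4 * hidden), hidden, 4 * hidden), f"{name}.wh"
        )
        bias = np.zeros(4 * hidden, dtype=np.float32)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(bias, f"{name}.b")

    def run(self, x: Tensor, reverse: bool = False) -> Tensor:
        return lstm_last(x, self.wx.tensor, self.wh.tensor, self.b.tensor, reverse=reverse)


class BiLSTM(Layer):
    """Bidirectional LSTM over the time axis of (N, C, T).

    Returns the concatenation of the final hidden state of each direction,
    shape (N, 2 * hidden).
    """

    def __init__(self, input_size: int, hidden: int, name: str = "bilstm", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.fwd = _LSTMDirection(input_size, hidden, f"{name}.fwd", rng)
        self.bwd = _LSTMDirection(input_size, hidden, f"{name}.bwd", rng)

    def forward(self, x: Tensor) -> Tensor:
        return concat([self.fwd.run(x), self.bwd.run(x, reverse=True)], axis=1)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
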