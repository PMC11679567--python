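"""Neural-network building blocks on top of the autodiff engine.

Layers mirror the familiar torch-style API surface (``Conv1d``,
``ConvTranspose1d``, ``BatchNorm1d`` ...) but are deliberately minimal: 1-D
signals, stride-1 convolutions (stride-2 upsampling via input dilation),
float64 math.  Every layer knows how to report its trainable parameter count
and the floating-point cost of one forward pass, which the network-level
budget checks rely on.

FLOP convention: one multiply-accumulate = 2 FLOPs; batch-normalization,
activations and pooling are counted once per output element.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Conv1d", "ConvTranspose1d", "BatchNorm1d", "ELU",
    "AvgPool1d", "Linear", "Sequential",
]


class Module:
    """Base class: parameter discovery, train/eval mode, counting."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data.copy()
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                state[key] = v.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        state[f"{key}.{i}"] = item.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.array(state[key], dtype=np.float64))
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.array(state[f"{key}.{i}"],
                                             dtype=np.float64)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_kaiming(rng, (out_channels, in_channels,
                                            kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, padding=self.padding)

    def out_len(self, L: int) -> int:
        return L + 2 * self.padding - self.kernel_size + 1

    def flops(self, L: int) -> int:
        Lout = self.out_len(L)
        macs = self.kernel_size * self.in_channels * self.out_channels * Lout
        return 2 * macs + self.out_channels * Lout  # + bias adds


class ConvTranspose1d(Module):
    """Stride-2 transposed convolution, realized as dilation + convolution.

    With kernel 4, stride 2, implicit padding 1 the output length is exactly
    2x the input length.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int = 4, stride: int = 2, padding: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_kaiming(rng, (out_channels, in_channels,
                                            kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        dil = x.dilate_last(self.stride)
        w = self.weight.flip_last()
        y = dil.conv1d(w, self.bias, padding=self.kernel_size - 1)
        # trim to the conventional transposed-conv output length
        Lout = self.out_len(x.shape[-1])
        start = self.padding
        return y[..., start:start + Lout]

    def out_len(self, L: int) -> int:
        return (L - 1) * self.stride - 2 * self.padding + self.kernel_size

    def flops(self, L: int) -> int:
        Lout = self.out_len(L)
        macs = self.kernel_size * self.in_channels * self.out_channels * Lout
        return 2 * macs + self.out_channels * Lout


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, time) with running stats."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mu) / (var + self.eps) ** 0.5
        g = self.gamma.reshape(1, self.num_features, 1)
        b = self.beta.reshape(1, self.num_features, 1)
        return xhat * g + b

    def flops(self, L: int) -> int:
        return self.num_features * L  # once per element

    def out_len(self, L: int) -> int:
        return L


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.elu(self.alpha)

    def flops(self, L: int) -> int:
        return L  # per element, channel count folded in by caller

    def out_len(self, L: int) -> int:
        return L


class AvgPool1d(Module):
    """Average pooling, kernel 2 / stride 2, ceil mode via edge replication."""

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import concat
        L = x.shape[-1]
        if L % 2 == 1:
            x = concat([x, x[..., -1:]], axis=x.ndim - 1)
        return (x[..., ::2] + x[..., 1::2]) * 0.5

    def out_len(self, L: int) -> int:
        return -(-L // 2)  # ceil division

    def flops(self, L: int) -> int:
        return self.out_len(L)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_kaiming(rng, (in_features, out_features),
                                      in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def flops(self, n: int = 1) -> int:
        return n * (2 * self.in_features * self.out_features
                    + self.out_features)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
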