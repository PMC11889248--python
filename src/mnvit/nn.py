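"""Neural-network layers for the micronucleus classifier.

Conventions follow the MobileViT family: convolutions are bias-free and
normally followed by batch normalization and SiLU; transformer encoder
layers are pre-norm with learned qkv/out/ffn biases.  All modules operate
on :class:`~mnvit.tensor.Tensor` in NCHW (images) or (B, T, D) (sequences)
layout and expose named parameters for checkpointing and audits.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat, conv2d, depthwise_conv2d, softmax

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "LayerNorm", "Linear", "SiLU", "Sigmoid", "Identity",
    "GlobalAvgPool", "MultiheadSelfAttention", "TransformerEncoderLayer",
    "ConvBNSiLU",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: named parameters/buffers, train/eval mode, submodules."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, _ in self._buffers.items():
            yield (prefix + n, getattr(self, n))
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            out[n] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_p = dict(self.named_parameters())
        own_b = dict(self._iter_buffer_slots())
        missing = []
        for n, p in own_p.items():
            if n in state:
                if state[n].shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {n}")
                p.data[...] = state[n]
            else:
                missing.append(n)
        for n, (mod, attr) in own_b.items():
            if n in state:
                arr = getattr(mod, attr)
                arr[...] = state[n]
            else:
                missing.append(n)
        if strict and missing:
            raise KeyError(f"missing keys in state dict: {missing[:5]}...")
        return missing

    def _iter_buffer_slots(self, prefix: str = ""):
        for n in self._buffers:
            yield (prefix + n, (self, n))
        for mn, m in self._modules.items():
            yield from m._iter_buffer_slots(prefix + mn + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


# Module-level generator used only for weight init; reseeded by model builders.
_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """Bias-free dense convolution (square kernel, symmetric 'same' padding
    unless overridden)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, bias: bool = False):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_kaiming(_INIT_RNG, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.last_out_shape: tuple | None = None

    def forward(self, x):
        out = conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        self.last_out_shape = out.shape
        return out

    def param_count(self) -> int:
        n = self.weight.size
        if self.bias is not None:
            n += self.bias.size
        return n

    def macs(self) -> int:
        _, _, ho, wo = self.last_out_shape
        return self.kernel ** 2 * self.in_channels * self.out_channels * ho * wo


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None):
        super().__init__()
        self.channels, self.kernel, self.stride = channels, kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Parameter(_kaiming(_INIT_RNG, (channels, kernel, kernel), kernel * kernel))
        self.last_out_shape: tuple | None = None

    def forward(self, x):
        out = depthwise_conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        self.last_out_shape = out.shape
        return out

    def macs(self) -> int:
        _, _, ho, wo = self.last_out_shape
        return self.kernel ** 2 * self.channels * ho * wo


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.weight + self.bias


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming(_INIT_RNG, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None
        self.last_out_shape: tuple | None = None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        self.last_out_shape = out.shape
        return out

    def macs(self) -> int:
        lead = int(np.prod(self.last_out_shape[:-1]))
        return lead * self.in_features * self.out_features


class GlobalAvgPool(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))


class ConvBNSiLU(Sequential):
    """The MobileViT workhorse: bias-free conv + BN + SiLU."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1):
        super().__init__(Conv2d(cin, cout, kernel, stride=stride),
                         BatchNorm2d(cout), SiLU())


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError("embedding dim must divide evenly across heads")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim)
        self.proj = Linear(dim, dim)
        self.last_seq_shape: tuple | None = None

    def forward(self, x):
        b, t, d = x.shape
        self.last_seq_shape = (b, t, d)
        qkv = self.qkv(x).reshape(b, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)

    def attention_macs(self) -> int:
        b, t, _ = self.last_seq_shape
        # q@k^T and att@v, per head
        return 2 * b * self.heads * t * t * self.head_dim


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: LN -> MHSA -> +res, LN -> FFN(SiLU) -> +res."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float = 2.0):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).silu())
        return x
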