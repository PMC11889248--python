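"""Channel-attention operators: squeeze-and-excitation (SE) and the
normalization-based attention module (NAM).

SE pools each channel of a feature map to a scalar (squeeze), passes the
pooled vector through a two-layer bottleneck MLP with a sigmoid output
(excite), and rescales the channels by the resulting weights in (0, 1).

NAM normalizes the input feature map, derives per-element attention weights
by a sigmoid over a learned 1x1 convolution of the normalized features,
multiplies those weights into the *original* features, and reconstructs the
result with a second 1x1 convolution:

    x_hat = normalize(x);  A = sigmoid(f_att(x_hat));  Y = x * A;  Z = f_recon(Y)

Two surfaces are provided: pure-numpy functional forms operating on single
(C, H, W) feature maps — the contracts unit tests exercise — and trainable
:class:`~mnvit.nn.Module` counterparts used inside the network blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Tensor

__all__ = [
    "FeatureMap", "ChannelStats", "ExciteParams", "ChannelWeights", "NamState",
    "se_squeeze", "se_excite", "se_block", "nam_attention",
    "SEBlock", "NAM",
]


# ---------------------------------------------------------------------------
# Functional forms on (C, H, W) numpy arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureMap:
    """A single (channels, height, width) real-valued feature map."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("feature map must be rank 3: (channel, row, column)")
        if min(v.shape) < 1:
            raise ValueError("all feature-map dimensions must be >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class ChannelStats:
    """One pooled scalar per channel (the squeeze output Z_c)."""

    z: np.ndarray


@dataclass(frozen=True)
class ExciteParams:
    """Bottleneck MLP of the excitation stage: s = sigmoid(w2 @ relu(w1 @ z)).

    ``w1`` maps C -> C/r, ``w2`` maps C/r -> C; biases are off by default so
    the operator is exactly the two-matrix form.
    """

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self):
        w1 = np.asarray(self.w1, dtype=np.float64)
        w2 = np.asarray(self.w2, dtype=np.float64)
        if w1.ndim != 2 or w2.ndim != 2 or w1.shape[0] != w2.shape[1] or w1.shape[1] != w2.shape[0]:
            raise ValueError("excitation matrices must chain: w2 (C x C/r) after w1 (C/r x C)")
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)

    @classmethod
    def random(cls, channels: int, reduction: int, rng: np.random.Generator,
               scale: float = 0.1) -> "ExciteParams":
        hidden = max(1, channels // reduction)
        return cls(w1=rng.normal(0, scale, (hidden, channels)),
                   w2=rng.normal(0, scale, (channels, hidden)))


@dataclass(frozen=True)
class ChannelWeights:
    """Per-channel excitation weights, each strictly inside (0, 1)."""

    s: np.ndarray


@dataclass(frozen=True)
class NamState:
    """Intermediates of one NAM pass, kept for inspection and testing."""

    x_hat: np.ndarray
    a: np.ndarray
    y: np.ndarray
    z_out: np.ndarray


def _sigmoid(v: np.ndarray) -> np.ndarray:
    # clipped to the open interval so saturated weights stay strictly
    # inside (0, 1) as the attention contract requires
    s = 1.0 / (1.0 + np.exp(-v))
    return np.clip(s, 1e-12, 1.0 - 1e-12)


def se_squeeze(x: FeatureMap) -> ChannelStats:
    """Global average pooling: z[c] = mean over (i, j) of x[c, i, j]."""
    return ChannelStats(z=x.values.mean(axis=(1, 2)))


def se_excite(z: ChannelStats, p: ExciteParams) -> ChannelWeights:
    """s = sigmoid(w2 @ relu(w1 @ z)); every entry lands strictly in (0, 1)."""
    zv = np.asarray(z.z, dtype=np.float64)
    if p.w1.shape[1] != zv.shape[0]:
        raise ValueError(f"w1 expects {p.w1.shape[1]} channels, got {zv.shape[0]}")
    hidden = np.maximum(p.w1 @ zv, 0.0)
    return ChannelWeights(s=_sigmoid(p.w2 @ hidden))


def se_block(x: FeatureMap, p: ExciteParams) -> FeatureMap:
    """Rescale every channel of ``x`` by its excitation weight."""
    s = se_excite(se_squeeze(x), p).s
    return FeatureMap(values=x.values * s[:, None, None])


def nam_attention(
    x: FeatureMap,
    norm_mean: np.ndarray,
    norm_std: np.ndarray,
    f_att_weight: np.ndarray,
    f_recon_weight: np.ndarray,
    f_att_bias: np.ndarray | None = None,
) -> tuple[FeatureMap, NamState]:
    """Normalize -> weight -> reconstruct.

    ``norm_mean``/``norm_std`` are per-channel normalization statistics
    (length C); ``f_att_weight`` and ``f_recon_weight`` are 1x1 channel-mixing
    kernels of shape (C, C).  Returns the reconstructed map and all
    intermediates.
    """
    mean = np.asarray(norm_mean, dtype=np.float64)
    std = np.asarray(norm_std, dtype=np.float64)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(std)) and np.all(std > 0)):
        raise ValueError("normalization statistics must be finite with positive std")
    c = x.channels
    x_hat = (x.values - mean[:, None, None]) / std[:, None, None]
    w_att = np.asarray(f_att_weight, dtype=np.float64).reshape(c, c)
    pre = np.einsum("dc,chw->dhw", w_att, x_hat)
    if f_att_bias is not None:
        pre = pre + np.asarray(f_att_bias, dtype=np.float64)[:, None, None]
    a = _sigmoid(pre)
    y = x.values * a
    w_rec = np.asarray(f_recon_weight, dtype=np.float64).reshape(c, c)
    z_out = np.einsum("dc,chw->dhw", w_rec, y)
    return FeatureMap(values=z_out), NamState(x_hat=x_hat, a=a, y=y, z_out=z_out)


# ---------------------------------------------------------------------------
# Trainable modules
# ---------------------------------------------------------------------------

class SEBlock(nn.Module):
    """Squeeze-and-excitation over an NCHW tensor.

    The bottleneck uses ReLU, a sigmoid output and no biases, so with zero
    weights every channel is scaled by exactly 0.5.
    """

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        hidden = max(1, channels // reduction)
        self.channels, self.reduction = channels, reduction
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)

    def forward(self, x):
        z = x.mean(axis=(2, 3))              # (N, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()
        return x * s.reshape(s.shape[0], s.shape[1], 1, 1)


class NAM(nn.Module):
    """Normalization-based attention over an NCHW tensor.

    ``use_bn_scale_weights`` switches to the variant where attention comes
    from the normalization layer's own scale factors (weights proportional
    to |gamma|) instead of a learned 1x1 convolution of the normalized map.
    """

    def __init__(self, channels: int, use_bn_scale_weights: bool = False):
        super().__init__()
        self.channels = channels
        self.use_bn_scale_weights = use_bn_scale_weights
        self.norm = nn.BatchNorm2d(channels)
        if not use_bn_scale_weights:
            self.f_att = nn.Conv2d(channels, channels, kernel=1)
            self.f_recon = nn.Conv2d(channels, channels, kernel=1)

    def forward(self, x):
        x_hat = self.norm(x)
        if self.use_bn_scale_weights:
            gamma = self.norm.weight
            gabs = Tensor(np.abs(gamma.data))
            w = gabs * (1.0 / max(float(gabs.data.sum()), 1e-12))
            a = (x_hat * w.reshape(1, -1, 1, 1)).sigmoid()
            return x * a
        a = self.f_att(x_hat).sigmoid()
        y = x * a
        return self.f_recon(y)
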