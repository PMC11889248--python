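"""Building blocks of the micronucleus classifier.

* the convolution decomposition (a channel-wise depthwise stage, "Depth-Conv",
  followed by a 1x1 pixel-wise fusion stage, "PFCL") that replaces a standard
  k x k convolution;
* SEDD — depthwise separable convolution wrapped with SE channel attention;
* the MV2 inverted-residual block (expand 1x1 -> depthwise 3x3 -> project
  1x1) with an optional attention stage on the expanded channels (MV2-DD);
* patch unfold/fold between feature maps and token sequences;
* the MobileViT block: local convolutional representation, transformer
  encoder over unfolded patches, fold, and convolutional fusion with the
  input — with optional decomposition and attention (MobileViT block-DD).

Parameter bookkeeping matters here: the decomposed form of a k x k
convolution costs k^2*C_in + C_in*C_out weights against k^2*C_in*C_out for
the standard form, and batch normalization is attached only after the
pointwise stage so the normalization cost is identical in both forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import NAM, SEBlock
from .tensor import Tensor, concat

__all__ = [
    "ConvSpec", "TransformerSpec", "BlockConfig", "conv_param_count",
    "DecomposedConv", "SEDD", "MV2Block", "MobileViTBlock",
    "unfold_patches", "fold_patches",
]


# ---------------------------------------------------------------------------
# Specs and closed-form parameter counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    """Shape description of one convolution site."""

    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    groups: int = 1
    bias: bool = False

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be a positive odd integer")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("groups must divide both channel counts")
        if min(self.in_channels, self.out_channels, self.stride, self.groups) < 1:
            raise ValueError("channels, stride and groups must be positive")


def conv_param_count(spec: ConvSpec, decomposed: bool) -> int:
    """Weight count of a convolution site, standard or decomposed.

    Standard: k^2 * C_in * C_out / groups (+ C_out if biased).
    Decomposed (depthwise k x k + pointwise 1x1, bias-free):
    k^2 * C_in + C_in * C_out.
    """
    k, cin, cout = spec.kernel, spec.in_channels, spec.out_channels
    if decomposed:
        return k * k * cin + cin * cout
    n = k * k * cin * cout // spec.groups
    if spec.bias:
        n += cout
    return n


@dataclass(frozen=True)
class TransformerSpec:
    dim: int
    depth: int
    heads: int = 4
    mlp_ratio: float = 2.0
    patch_h: int = 2
    patch_w: int = 2


@dataclass(frozen=True)
class BlockConfig:
    in_channels: int
    out_channels: int
    expansion: int = 2
    stride: int = 1
    attention: str = "none"          # none | se | nam
    decomposed: bool = False
    transformer: TransformerSpec | None = None
    attention_first: bool = True     # MobileViT block: attention before the 3x3

    def __post_init__(self):
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.attention not in ("none", "se", "nam"):
            raise ValueError(f"unknown attention kind {self.attention!r}")


def _make_attention(kind: str, channels: int) -> nn.Module:
    if kind == "se":
        return SEBlock(channels)
    if kind == "nam":
        return NAM(channels)
    return nn.Identity()


# ---------------------------------------------------------------------------
# Decomposed convolution and SEDD
# ---------------------------------------------------------------------------

class DecomposedConv(nn.Module):
    """Depth-Conv + PFCL replacement for a standard k x k convolution.

    The depthwise stage filters each channel independently with its own
    k x k kernel; the pointwise 1x1 stage fuses information across channels
    and sets the output width.  Normalization and SiLU follow the pointwise
    stage only.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 norm_act: bool = True):
        super().__init__()
        self.spec = ConvSpec(kernel, cin, cout, stride=stride)
        self.depthwise = nn.DepthwiseConv2d(cin, kernel, stride=stride)
        self.pointwise = nn.Conv2d(cin, cout, 1)
        self.post = nn.Sequential(nn.BatchNorm2d(cout), nn.SiLU()) if norm_act else nn.Identity()

    def forward(self, x):
        return self.post(self.pointwise(self.depthwise(x)))


class SEDD(nn.Module):
    """Depthwise 3x3 separable stage wrapped with channel attention.

    With ``attention='se'`` this is the SE-based deep separation
    decentralization unit; ``'nam'`` swaps in NAM; ``'none'`` leaves the bare
    depthwise stage (the plain inverted-residual form).
    """

    def __init__(self, channels: int, stride: int = 1, attention: str = "se"):
        super().__init__()
        self.depthwise = nn.DepthwiseConv2d(channels, 3, stride=stride)
        self.norm = nn.BatchNorm2d(channels)
        self.act = nn.SiLU()
        self.attention = _make_attention(attention, channels)

    def forward(self, x):
        return self.attention(self.act(self.norm(self.depthwise(x))))


class MV2Block(nn.Module):
    """Inverted residual: expand 1x1 -> (SEDD | depthwise 3x3) -> project 1x1.

    The projection is linear (no activation), and the shortcut is used when
    stride is 1 and the channel count is preserved.
    """

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        if cfg.transformer is not None:
            raise ValueError("MV2Block takes a config without a transformer")
        self.cfg = cfg
        hidden = cfg.in_channels * cfg.expansion
        self.expand = nn.ConvBNSiLU(cfg.in_channels, hidden, 1)
        self.sedd = SEDD(hidden, stride=cfg.stride, attention=cfg.attention)
        self.project = nn.Sequential(nn.Conv2d(hidden, cfg.out_channels, 1),
                                     nn.BatchNorm2d(cfg.out_channels))
        self.use_residual = cfg.stride == 1 and cfg.in_channels == cfg.out_channels

    def forward(self, x):
        out = self.project(self.sedd(self.expand(x)))
        if self.use_residual:
            out = out + x
        return out


# ---------------------------------------------------------------------------
# Patch unfold / fold
# ---------------------------------------------------------------------------

def unfold_patches(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Cut a (C, H, W) map into (H/ph * W/pw) patches of ph*pw tokens.

    Returns an array of shape (n_patches, ph*pw, C); raises when the patch
    size does not divide the spatial dimensions (no implicit padding).
    """
    x = np.asarray(x)
    c, h, w = x.shape
    if h % ph or w % pw:
        raise ValueError(f"patch size ({ph},{pw}) must divide feature map ({h},{w})")
    nh, nw = h // ph, w // pw
    t = x.reshape(c, nh, ph, nw, pw).transpose(1, 3, 2, 4, 0)
    return t.reshape(nh * nw, ph * pw, c)


def fold_patches(seq: np.ndarray, h: int, w: int, ph: int, pw: int) -> np.ndarray:
    """Exact inverse of :func:`unfold_patches`."""
    seq = np.asarray(seq)
    nh, nw = h // ph, w // pw
    if h % ph or w % pw or seq.shape[:2] != (nh * nw, ph * pw):
        raise ValueError("sequence shape inconsistent with (H, W, ph, pw)")
    c = seq.shape[2]
    t = seq.reshape(nh, nw, ph, pw, c).transpose(4, 0, 2, 1, 3)
    return t.reshape(c, h, w)


def _resize_nearest(x: Tensor, h2: int, w2: int) -> Tensor:
    n, c, h, w = x.shape
    if (h, w) == (h2, w2):
        return x
    iy = np.minimum((np.arange(h2) * h // h2), h - 1)
    ix = np.minimum((np.arange(w2) * w // w2), w - 1)
    return x[:, :, iy, :][:, :, :, ix]


def _unfold_tensor(x: Tensor, ph: int, pw: int) -> tuple[Tensor, tuple]:
    n, c, h, w = x.shape
    if h % ph or w % pw:
        raise ValueError(f"patch size ({ph},{pw}) must divide feature map ({h},{w})")
    nh, nw = h // ph, w // pw
    t = x.reshape(n, c, nh, ph, nw, pw).transpose(0, 3, 5, 2, 4, 1)
    return t.reshape(n * ph * pw, nh * nw, c), (n, c, h, w)


def _fold_tensor(seq: Tensor, info: tuple, ph: int, pw: int) -> Tensor:
    n, c, h, w = info
    nh, nw = h // ph, w // pw
    t = seq.reshape(n, ph, pw, nh, nw, c).transpose(0, 5, 3, 1, 4, 2)
    return t.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# MobileViT block
# ---------------------------------------------------------------------------

class MobileViTBlock(nn.Module):
    """Local conv representation -> unfold -> transformer -> fold -> fusion.

    Layout (C input channels, d embedding dim):

      [attention]  -> 3x3 conv C->C  -> 1x1 conv C->d      (local representation)
      unfold (ph x pw patches) -> L pre-norm encoder layers -> LayerNorm -> fold
      1x1 conv d->C  -> concat with input (2C) -> 3x3 fusion conv 2C->C

    With ``cfg.decomposed`` both 3x3 convolutions are replaced by
    Depth-Conv + PFCL; ``cfg.attention`` places SE or NAM in the local
    representation (before the 3x3 by default).  Spatial size is preserved.
    """

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        if cfg.transformer is None:
            raise ValueError("MobileViTBlock requires a transformer spec")
        self.cfg = cfg
        c, tr = cfg.in_channels, cfg.transformer
        if cfg.out_channels != c:
            raise ValueError("MobileViT block preserves the channel count")
        self.attention = _make_attention(cfg.attention, c)
        if cfg.decomposed:
            self.local_conv = DecomposedConv(c, c, 3)
            self.fusion = DecomposedConv(2 * c, c, 3)
        else:
            self.local_conv = nn.ConvBNSiLU(c, c, 3)
            self.fusion = nn.ConvBNSiLU(2 * c, c, 3)
        self.local_proj = nn.Conv2d(c, tr.dim, 1)
        self.transformer = nn.Sequential(
            *[nn.TransformerEncoderLayer(tr.dim, tr.heads, tr.mlp_ratio)
              for _ in range(tr.depth)])
        self.post_norm = nn.LayerNorm(tr.dim)
        self.global_proj = nn.ConvBNSiLU(tr.dim, c, 1)

    def forward(self, x):
        tr = self.cfg.transformer
        y = x
        if self.cfg.attention_first:
            y = self.attention(y)
            y = self.local_conv(y)
        else:
            y = self.local_conv(y)
            y = self.attention(y)
        y = self.local_proj(y)
        # feature maps whose sides the patch does not divide are resized to
        # the next multiple for the transformer and resized back after fold
        n, d, h, w = y.shape
        h2 = -(-h // tr.patch_h) * tr.patch_h
        w2 = -(-w // tr.patch_w) * tr.patch_w
        y = _resize_nearest(y, h2, w2)
        seq, info = _unfold_tensor(y, tr.patch_h, tr.patch_w)
        seq = self.post_norm(self.transformer(seq))
        y = _fold_tensor(seq, (info[0], tr.dim, h2, w2), tr.patch_h, tr.patch_w)
        y = _resize_nearest(y, h, w)
        y = self.global_proj(y)
        return self.fusion(concat([x, y], axis=1))
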