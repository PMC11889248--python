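"""Assembly of the full micronucleus classifier and its ablation grid.

The macro-structure is the smallest MobileViT scale: a 3x3 stride-2 stem to
16 channels; a trunk of inverted-residual (MV2) stages at widths
16/24/24/24/48/64/80 with expansion 2; three transformer stages with
embedding dims 64/80/96 and encoder depths (2, 4, 3); a 1x1 expansion to
320; global average pooling; and a linear classification head.  With a
1000-class head this trunk carries exactly 1,272,024 trainable parameters;
decomposing the two 3x3 convolutions of each transformer stage
(Depth-Conv + PFCL) removes 302,016 of them, leaving 970,008.

Ablation variants toggle the decomposition and place SE or NAM attention in
the MV2 blocks and/or the MobileViT blocks; ``tr1``/``tr3`` variants set
every transformer stage depth to 1 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .blocks import BlockConfig, MV2Block, MobileViTBlock, TransformerSpec, conv_param_count, ConvSpec

__all__ = [
    "ModelVariantConfig", "ModelAudit", "MobileViTMN", "PRESETS",
    "build_model", "count_parameters", "count_macs", "audit_variant_grid",
    "decomposition_savings",
]

# trunk widths / dims of the smallest MobileViT scale
_STEM_OUT = 16
_MV2_PLAN = [  # (cin, cout, stride)
    (16, 16, 1),
    (16, 24, 2), (24, 24, 1), (24, 24, 1),
]
_STAGES = [  # (cin, cout, stride of the leading MV2, embed dim)
    (24, 48, 2, 64),
    (48, 64, 2, 80),
    (64, 80, 2, 96),
]
_EXP_OUT = 320
_EXPANSION = 2
_DEFAULT_DEPTHS = (2, 4, 3)


@dataclass(frozen=True)
class ModelVariantConfig:
    """Declarative description of one ablation variant."""

    name: str
    decomposed: bool = False
    mv2_attention: str = "none"     # none | se | nam
    mb_attention: str = "none"
    transformer_depths: tuple[int, int, int] = _DEFAULT_DEPTHS
    num_classes: int = 1000
    input_size: int = 224
    se_reduction: int = 4
    patch_size: int = 2
    heads: int = 4
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if len(self.transformer_depths) != 3 or min(self.transformer_depths) < 1:
            raise ValueError("transformer_depths must be three integers >= 1")
        for a in (self.mv2_attention, self.mb_attention):
            if a not in ("none", "se", "nam"):
                raise ValueError(f"unknown attention kind {a!r}")
        if self.num_classes < 1 or self.input_size < 1:
            raise ValueError("num_classes and input_size must be positive")


def _preset(name: str, **kw) -> ModelVariantConfig:
    return ModelVariantConfig(name=name, **kw)


#: One named configuration per ablation row, keyed by the row label.
PRESETS: dict[str, ModelVariantConfig] = {
    "MobileViT": _preset("MobileViT"),
    "Model_DSC": _preset("Model_DSC", decomposed=True),
    "MV2_SE": _preset("MV2_SE", decomposed=True, mv2_attention="se"),
    "MV2_SE_Mb_tr1": _preset("MV2_SE_Mb_tr1", decomposed=True, mv2_attention="se",
                             transformer_depths=(1, 1, 1)),
    "MV2_SE_Mb_tr3": _preset("MV2_SE_Mb_tr3", decomposed=True, mv2_attention="se",
                             transformer_depths=(3, 3, 3)),
    "MV2_NAM": _preset("MV2_NAM", decomposed=True, mv2_attention="nam"),
    "MV2_NAM_Mb_tr1": _preset("MV2_NAM_Mb_tr1", decomposed=True, mv2_attention="nam",
                              transformer_depths=(1, 1, 1)),
    "MV2_NAM_Mb_tr3": _preset("MV2_NAM_Mb_tr3", decomposed=True, mv2_attention="nam",
                              transformer_depths=(3, 3, 3)),
    "Mb_SE": _preset("Mb_SE", decomposed=True, mb_attention="se"),
    "Mb_NAM": _preset("Mb_NAM", decomposed=True, mb_attention="nam"),
    "MV2_SE_Mb_NAM": _preset("MV2_SE_Mb_NAM", decomposed=True,
                             mv2_attention="se", mb_attention="nam"),
    "MV2_NAM_Mb_SE": _preset("MV2_NAM_Mb_SE", decomposed=True,
                             mv2_attention="nam", mb_attention="se"),
}


class MobileViTMN(nn.Module):
    """The assembled classifier."""

    def __init__(self, cfg: ModelVariantConfig):
        super().__init__()
        self.cfg = cfg
        att = cfg.mv2_attention
        self.stem = nn.ConvBNSiLU(3, _STEM_OUT, 3, stride=2)
        mv2 = [MV2Block(BlockConfig(ci, co, _EXPANSION, s, attention=att))
               for ci, co, s in _MV2_PLAN]
        self.trunk = nn.Sequential(*mv2)
        stages = []
        for (ci, co, s, dim), depth in zip(_STAGES, cfg.transformer_depths):
            stages.append(MV2Block(BlockConfig(ci, co, _EXPANSION, s, attention=att)))
            tr = TransformerSpec(dim=dim, depth=depth, heads=cfg.heads,
                                 mlp_ratio=cfg.mlp_ratio,
                                 patch_h=cfg.patch_size, patch_w=cfg.patch_size)
            stages.append(MobileViTBlock(BlockConfig(
                co, co, attention=cfg.mb_attention, decomposed=cfg.decomposed,
                transformer=tr)))
        self.stages = nn.Sequential(*stages)
        self.head_conv = nn.ConvBNSiLU(_STAGES[-1][1], _EXP_OUT, 1)
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(_EXP_OUT, cfg.num_classes)

    def forward(self, x):
        x = self.stages(self.trunk(self.stem(x)))
        return self.fc(self.pool(self.head_conv(x)))

    def logits(self, images: np.ndarray) -> np.ndarray:
        """Convenience inference entry point on an (N, 3, H, W) array."""
        from .tensor import Tensor
        return self.forward(Tensor(images)).data


def build_model(cfg: ModelVariantConfig | str, seed: int = 0) -> MobileViTMN:
    """Build a variant from a config or a preset name, with seeded init."""
    if isinstance(cfg, str):
        if cfg not in PRESETS:
            raise KeyError(f"unknown preset {cfg!r}; known: {sorted(PRESETS)}")
        cfg = PRESETS[cfg]
    nn.seed_init(seed)
    return MobileViTMN(cfg)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars (normalization running stats excluded)."""
    return sum(p.data.size for p in model.parameters())


def per_layer_parameters(model: nn.Module) -> list[tuple[str, int]]:
    return [(name, p.data.size) for name, p in model.named_parameters()]


def count_macs(model: MobileViTMN, input_size: int | None = None) -> int:
    """Multiply-accumulate count of one forward pass.

    Convention: every convolution contributes k^2 * (C_in/groups) * C_out *
    H_out * W_out, every linear layer (including transformer qkv/out/ffn
    projections) contributes tokens * in_features * out_features, and each
    self-attention layer adds its two sequence-level matmuls
    (2 * B * heads * T^2 * head_dim).  Elementwise and normalization work is
    not counted.
    """
    from .tensor import Tensor

    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    model(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    model.train(was_training)
    total = 0
    for m in model.modules():
        if isinstance(m, (nn.Conv2d, nn.DepthwiseConv2d, nn.Linear)):
            total += m.macs()
        if isinstance(m, nn.MultiheadSelfAttention):
            total += m.attention_macs()
    return total


@dataclass
class ModelAudit:
    preset: str
    parameters: int
    macs: int
    input_size: int
    per_layer: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.per_layer and sum(n for _, n in self.per_layer) != self.parameters:
            raise ValueError("per-layer parameter breakdown does not sum to the total")


def decomposition_savings(widths=(48, 64, 80), kernel: int = 3) -> int:
    """Closed-form weight savings of decomposing both 3x3 convs per stage.

    Per stage width C the local C->C conv saves (k^2-1)C^2 - k^2 C and the
    2C->C fusion conv saves 2(k^2-1)C^2 - 2 k^2 C; at k=3 these are
    8C^2 - 9C and 16C^2 - 18C.
    """
    total = 0
    for c in widths:
        local = ConvSpec(kernel, c, c)
        fusion = ConvSpec(kernel, 2 * c, c)
        total += conv_param_count(local, False) - conv_param_count(local, True)
        total += conv_param_count(fusion, False) - conv_param_count(fusion, True)
    return total


def audit_variant_grid(presets: list[str] | None = None, num_classes: int = 1000,
                       input_size: int = 224, with_macs: bool = True) -> pd.DataFrame:
    """One audit row per preset; includes the baseline-vs-DSC difference.

    Returns a DataFrame with columns (preset, parameters, macs, input_size,
    param_delta_vs_baseline).  MAC counting needs a forward pass, so it can
    be switched off for quick parameter-only audits.
    """
    names = list(presets) if presets else list(PRESETS)
    rows = []
    baseline_params = None
    for name in names:
        cfg = replace(PRESETS[name], num_classes=num_classes, input_size=input_size) \
            if name in PRESETS else ModelVariantConfig(name=name)
        model = build_model(cfg)
        params = count_parameters(model)
        audit = ModelAudit(
            preset=name, parameters=params,
            macs=count_macs(model, input_size) if with_macs else 0,
            input_size=input_size, per_layer=per_layer_parameters(model))
        if name == "MobileViT":
            baseline_params = params
        rows.append(audit)
    df = pd.DataFrame([{
        "preset": a.preset, "parameters": a.parameters, "macs": a.macs,
        "input_size": a.input_size} for a in rows])
    if baseline_params is not None:
        df["param_delta_vs_baseline"] = df["parameters"] - baseline_params
    return df
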