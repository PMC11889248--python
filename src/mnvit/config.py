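"""Run configuration: one validated YAML document drives every command.

Unknown keys are rejected so a typo in a config file fails loudly before
any artifact is written.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_total: int = 400
    positive_fraction: float = Field(0.065, gt=0, lt=1)
    side: int = 64
    easy_mode: bool = False
    background_range: tuple[float, float] | None = None
    nucleus_intensity_range: tuple[float, float] | None = None
    noise_std: float | None = None
    blur_sigma: float | None = None


class AugmentSection(_Strict):
    rotation_deg: float = 30.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)


class ModelSection(_Strict):
    preset: str = "MV2_SE_Mb_NAM"
    num_classes: int = 2
    input_size: int = 224


class TrainSection(_Strict):
    batch_size: int = 64
    initial_lr: float = 0.001
    epochs: int = 50
    input_side: int = 224
    freeze_trunk: bool = False


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/mnvit"
    synth: SynthSection = SynthSection()
    augment: AugmentSection = AugmentSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def digest(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]

    def image_spec(self):
        from .synthetic import SyntheticImageSpec, easy_spec

        if self.synth.easy_mode:
            return easy_spec(self.synth.side)
        kw = {}
        for name in ("background_range", "nucleus_intensity_range",
                     "noise_std", "blur_sigma"):
            val = getattr(self.synth, name)
            if val is not None:
                kw[name] = val
        return SyntheticImageSpec(side=self.synth.side, **kw)

    def augment_policy(self):
        from .pipeline import AugmentationPolicy

        a = self.augment
        return AugmentationPolicy(rotation_deg=a.rotation_deg, p_hflip=a.p_hflip,
                                  p_vflip=a.p_vflip, scale_range=a.scale_range)
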