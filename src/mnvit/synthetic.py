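"""Seeded synthetic micronucleus microscopy images.

Real micronucleus assays image Giemsa-stained cells: a bright, roughly
elliptical nucleus on a darker cytoplasm/background, where a positive cell
additionally carries one or more small round chromatin bodies (micronuclei)
near the nucleus boundary.  This module renders single-cell crops with that
morphology — ellipse nucleus with random orientation, optional satellite
blobs in a ring around the nucleus, Gaussian blur and additive noise — so
the full training/evaluation pipeline can run without any private data.

Everything is deterministic in (spec, label, seed); each sample keeps a
geometry record (nucleus and micronucleus parameters) for test assertions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticImageSpec", "ImageSample", "generate_cell_image",
    "generate_dataset", "easy_spec", "shifted_spec",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Rendering parameters for one synthetic cell crop.

    Lengths are fractions: nucleus axes of the image side, micronucleus
    radius of the nucleus *minor* axis.  Intensities live in [0, 1].
    """

    side: int = 64
    background_range: tuple[float, float] = (0.10, 0.25)
    nucleus_axis_range: tuple[float, float] = (0.22, 0.38)
    nucleus_intensity_range: tuple[float, float] = (0.65, 0.85)
    mn_count_range: tuple[int, int] = (1, 2)
    mn_radius_range: tuple[float, float] = (0.10, 0.33)
    mn_ring_range: tuple[float, float] = (1.15, 1.6)
    noise_std: float = 0.02
    blur_sigma: float = 0.7
    tint: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.side < 8:
            raise ValueError("image side must be >= 8 pixels")
        for lo, hi in (self.background_range, self.nucleus_intensity_range,
                       self.nucleus_axis_range, self.mn_radius_range):
            if not (0 <= lo <= hi):
                raise ValueError("ranges must satisfy 0 <= low <= high")
        if self.background_range[1] > 1 or self.nucleus_intensity_range[1] > 1:
            raise ValueError("intensities must stay within [0, 1]")
        if self.mn_count_range[0] < 1:
            raise ValueError("positive-class images need at least one micronucleus")
        if self.mn_radius_range[1] >= 1.0:
            raise ValueError("micronucleus radius must stay below the nucleus minor axis")
        # a micronucleus ring reaching past the image corner is unsatisfiable
        reach = (self.nucleus_axis_range[1] / 2) * self.mn_ring_range[1]
        if reach > 0.75:
            raise ValueError("micronucleus ring extends outside the image")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ImageSample:
    pixels: np.ndarray            # (side, side, 3) uint8
    label: int                    # 0 normal, 1 micronucleus
    seed: int
    spec_digest: str
    geometry: dict = field(default_factory=dict)


def easy_spec(side: int = 64) -> SyntheticImageSpec:
    """High-contrast, noise-free variant for learnability checks."""
    return SyntheticImageSpec(side=side, background_range=(0.08, 0.12),
                              nucleus_intensity_range=(0.85, 0.95),
                              mn_count_range=(2, 3), mn_radius_range=(0.22, 0.33),
                              noise_std=0.0, blur_sigma=0.4)


def shifted_spec(side: int = 64) -> SyntheticImageSpec:
    """A domain-shifted variant (dimmer stain, more noise) for transfer tests."""
    return SyntheticImageSpec(side=side, background_range=(0.18, 0.30),
                              nucleus_intensity_range=(0.60, 0.75),
                              mn_count_range=(2, 3), mn_radius_range=(0.20, 0.30),
                              noise_std=0.05, blur_sigma=0.9)


def _ellipse_mask(side: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_cell_image(spec: SyntheticImageSpec, label: int,
                        rng_seed: int) -> ImageSample:
    """Render one labeled cell crop, deterministic in (spec, label, seed)."""
    if label not in (0, 1):
        raise ValueError("label must be 0 (normal) or 1 (micronucleus)")
    rng = np.random.default_rng(rng_seed)
    s = spec.side
    bg = rng.uniform(*spec.background_range)
    img = np.full((s, s), bg, dtype=np.float64)

    # nucleus: random ellipse near the image center
    ax1 = rng.uniform(*spec.nucleus_axis_range) * s / 2
    ax2 = rng.uniform(*spec.nucleus_axis_range) * s / 2
    a, b = max(ax1, ax2), min(ax1, ax2)
    theta = rng.uniform(0, np.pi)
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    nucleus_int = rng.uniform(*spec.nucleus_intensity_range)
    nucleus = _ellipse_mask(s, cx, cy, a, b, theta)
    img[nucleus] = nucleus_int

    geometry = {
        "background": bg,
        "nucleus": {"cx": cx, "cy": cy, "a": a, "b": b, "theta": theta,
                    "intensity": nucleus_int},
        "micronuclei": [],
    }

    if label == 1:
        lo, hi = spec.mn_count_range
        n_mn = int(rng.integers(lo, hi + 1))
        for _ in range(n_mn):
            r = rng.uniform(*spec.mn_radius_range) * b
            ring = rng.uniform(*spec.mn_ring_range)
            phi = rng.uniform(0, 2 * np.pi)
            # place on an ellipse-shaped ring just outside the nucleus boundary
            mx = cx + ring * (a + r) * np.cos(phi) * np.cos(theta) \
                 - ring * (b + r) * np.sin(phi) * np.sin(theta)
            my = cy + ring * (a + r) * np.cos(phi) * np.sin(theta) \
                 + ring * (b + r) * np.sin(phi) * np.cos(theta)
            mx = float(np.clip(mx, r + 1, s - r - 2))
            my = float(np.clip(my, r + 1, s - r - 2))
            blob = _ellipse_mask(s, mx, my, r, r, 0.0)
            img[blob] = nucleus_int
            geometry["micronuclei"].append({"cx": mx, "cy": my, "r": r,
                                            "intensity": nucleus_int})

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_std > 0:
        img = img + rng.normal(0, spec.noise_std, img.shape)
    img = np.clip(img, 0.0, 1.0)
    rgb = np.stack([img * t for t in spec.tint], axis=-1)
    pixels = np.round(rgb * 255).astype(np.uint8)
    return ImageSample(pixels=pixels, label=label, seed=rng_seed,
                       spec_digest=spec.digest(), geometry=geometry)


def generate_dataset(n_total: int, positive_fraction: float,
                     spec: SyntheticImageSpec, seed: int,
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate a labeled pool with a controlled positive fraction.

    Exactly ``round(n_total * positive_fraction)`` samples are positive
    (default study condition elsewhere: 0.065, the unaugmented test-set
    imbalance of a typical assay pool).  When ``out_dir`` is given, images
    are written as PNG and manifest paths point at them; otherwise paths are
    symbolic.  Returns (samples, manifest) with manifest columns
    path,label,split,origin,seed (split unassigned, origin raw).
    """
    if n_total < 2:
        raise ValueError("need at least two samples")
    if not 0 < positive_fraction < 1:
        raise ValueError("positive_fraction must lie strictly between 0 and 1")
    n_pos = int(round(n_total * positive_fraction))
    labels = np.array([1] * n_pos + [0] * (n_total - n_pos))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    seeds = rng.integers(0, 2**31 - 1, size=n_total)
    samples, rows = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (lab, sd) in enumerate(zip(labels, seeds)):
        sample = generate_cell_image(spec, int(lab), int(sd))
        name = f"cell_{i:05d}_l{lab}.png"
        if out is not None:
            iio.imwrite(out / name, sample.pixels)
            path = str(out / name)
        else:
            path = name
        samples.append(sample)
        rows.append({"path": path, "label": int(lab), "split": "",
                     "origin": "raw", "seed": int(sd)})
    return samples, pd.DataFrame(rows)
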