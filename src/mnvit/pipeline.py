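"""Dataset manifests, stratified splitting, augmentation and rebalancing.

The data strategy mirrors the imbalance-aware protocol the classifier is
built for: a stratified 6:2:2 train/val/test split; random rotation, flip
and scale augmentation; training-set rebalancing that oversamples the
minority (micronucleus) class with augmented copies while downsampling the
majority class; and a test split that is never augmented so evaluation
reflects the raw class distribution.

Manifests are pandas DataFrames with columns path,label,split,origin,seed;
augmented images are materialized next to their source files so every
manifest path names a distinct real image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import transform as sktf

__all__ = [
    "AugmentationPolicy", "split_dataset", "augment_image", "rebalance_train",
    "expand_val", "IDENTITY_POLICY",
    "load_manifest", "save_manifest", "load_split_arrays",
    "DEFAULT_SPLIT_RATIOS", "NORM_MEAN", "NORM_STD",
]

DEFAULT_SPLIT_RATIOS = (0.6, 0.2, 0.2)
MANIFEST_COLUMNS = ["path", "label", "split", "origin", "seed"]

# fixed per-channel standardization constants applied at load time
NORM_MEAN = 0.5
NORM_STD = 0.25


@dataclass(frozen=True)
class AugmentationPolicy:
    """Label-preserving geometric augmentation: rotate, flip, zoom."""

    rotation_deg: float = 30.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self):
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ValueError("scale range must be positive with min <= max")


IDENTITY_POLICY = AugmentationPolicy(rotation_deg=0.0, p_hflip=0.0, p_vflip=0.0,
                                     scale_range=(1.0, 1.0))


def _validate_manifest(manifest: pd.DataFrame):
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    if manifest["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")


def split_dataset(manifest: pd.DataFrame,
                  ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS,
                  seed: int = 0) -> pd.DataFrame:
    """Stratified train/val/test assignment, deterministic in ``seed``.

    Within each class the split counts are the largest-remainder rounding of
    the normalized ratios, so per-class proportions match within one sample.
    """
    _validate_manifest(manifest)
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    r = r / r.sum()
    classes = sorted(manifest["label"].unique())
    if len(classes) < 2:
        raise ValueError("both classes must be present before splitting")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    names = np.array(["train", "val", "test"])
    for cls in classes:
        idx = out.index[out["label"] == cls].to_numpy()
        if len(idx) < 3:
            raise ValueError(f"class {cls} has fewer samples than splits")
        perm = rng.permutation(idx)
        exact = r * len(idx)
        counts = np.floor(exact).astype(int)
        rem = len(idx) - counts.sum()
        order = np.argsort(-(exact - counts))
        counts[order[:rem]] += 1
        bounds = np.cumsum(counts)[:-1]
        for name, part in zip(names, np.split(perm, bounds)):
            out.loc[part, "split"] = name
    return out


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center with reflection padding (bilinear)."""
    return sktf.rotate(image, angle_deg, mode="reflect", order=1)


def augment_image(image: np.ndarray, policy: AugmentationPolicy,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one random rotation/flip/zoom draw; shape and dtype preserved.

    Rotation and zoom use reflection padding and bilinear interpolation; the
    zoom is followed by a center crop (zoom-in) or reflected pad (zoom-out)
    back to the input size.
    """
    img = np.asarray(image)
    was_uint8 = img.dtype == np.uint8
    work = img.astype(np.float64) / 255.0 if was_uint8 else img.astype(np.float64)
    angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    if angle != 0.0:
        work = rotate_image(work, angle)
    if rng.random() < policy.p_hflip:
        work = work[:, ::-1]
    if rng.random() < policy.p_vflip:
        work = work[::-1, :]
    scale = rng.uniform(*policy.scale_range)
    if scale != 1.0:
        h, w = work.shape[:2]
        zoomed = sktf.rescale(work, scale, channel_axis=-1 if work.ndim == 3 else None,
                              mode="reflect", order=1, anti_aliasing=scale < 1.0)
        zh, zw = zoomed.shape[:2]
        if zh >= h:
            top, left = (zh - h) // 2, (zw - w) // 2
            work = zoomed[top:top + h, left:left + w]
        else:
            pads = [((h - zh) // 2, h - zh - (h - zh) // 2),
                    ((w - zw) // 2, w - zw - (w - zw) // 2)]
            if work.ndim == 3:
                pads.append((0, 0))
            work = np.pad(zoomed, pads, mode="reflect")
    work = np.clip(work, 0.0, 1.0)
    return np.round(work * 255).astype(np.uint8) if was_uint8 else work.astype(image.dtype)


def rebalance_train(manifest: pd.DataFrame, policy: AugmentationPolicy,
                    target_ratio: float = 1.0, seed: int = 0,
                    majority_cap: int | None = None,
                    max_copies_per_image: int = 20) -> pd.DataFrame:
    """Rebalance the train split: downsample majority, augment minority.

    After rebalancing the train-split minority:majority count ratio is
    within 2% of ``target_ratio`` (default 1:1).  The majority class is
    randomly subsampled (optionally to ``majority_cap``); the minority class
    is expanded with augmented copies written next to their sources.  Val
    and test rows pass through untouched.
    """
    _validate_manifest(manifest)
    train = manifest[manifest["split"] == "train"]
    rest = manifest[manifest["split"] != "train"]
    counts = train["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("train split must contain both classes")
    # ties default to class 1 (micronucleus) as the minority, per the assay
    labels_sorted = sorted(counts.index, key=lambda c: (counts[c], -c))
    minority, majority = labels_sorted[0], labels_sorted[-1]
    rng = np.random.default_rng(seed)

    maj_rows = train[train["label"] == majority]
    min_rows = train[train["label"] == minority]
    n_maj = len(maj_rows) if majority_cap is None else min(len(maj_rows), majority_cap)
    n_min_target = int(round(target_ratio * n_maj))
    max_reachable = len(min_rows) * (1 + max_copies_per_image)
    if n_min_target > max_reachable:
        reachable = max_reachable / n_maj
        raise ValueError(
            f"target ratio {target_ratio} unreachable with augmentation cap; "
            f"achievable minority:majority ratio is at most {reachable:.2f}")

    keep_maj = maj_rows.sample(n=n_maj, random_state=int(rng.integers(2**31)))
    n_copies = max(0, n_min_target - len(min_rows))
    aug_rows = []
    if n_copies:
        sources = min_rows.sample(n=n_copies, replace=True,
                                  random_state=int(rng.integers(2**31)))
        for k, (_, src) in enumerate(sources.iterrows()):
            aug_seed = int(rng.integers(2**31))
            src_path = Path(src["path"])
            new_path = src_path.with_name(f"{src_path.stem}_aug{k:05d}.png")
            if src_path.exists():
                img = iio.imread(src_path)
                iio.imwrite(new_path, augment_image(img, policy,
                                                    np.random.default_rng(aug_seed)))
            aug_rows.append({"path": str(new_path), "label": src["label"],
                             "split": "train", "origin": "augmented",
                             "seed": aug_seed})
    out = pd.concat([rest, keep_maj, min_rows, pd.DataFrame(aug_rows)],
                    ignore_index=True)
    _validate_manifest(out)
    if (out.loc[out["split"] == "test", "origin"] == "augmented").any():
        raise AssertionError("test split must stay unaugmented")
    return out


def expand_val(manifest: pd.DataFrame, policy: AugmentationPolicy,
               factor: int = 2, seed: int = 0) -> pd.DataFrame:
    """Optionally augment the validation split by an integer factor per class.

    Each val image gains ``factor - 1`` augmented copies; train and test
    rows pass through untouched.
    """
    _validate_manifest(manifest)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    val = manifest[manifest["split"] == "val"]
    aug_rows = []
    k = 0
    for _, src in val.iterrows():
        for _ in range(factor - 1):
            aug_seed = int(rng.integers(2**31))
            src_path = Path(src["path"])
            new_path = src_path.with_name(f"{src_path.stem}_vaug{k:05d}.png")
            k += 1
            if src_path.exists():
                img = iio.imread(src_path)
                iio.imwrite(new_path, augment_image(img, policy,
                                                    np.random.default_rng(aug_seed)))
            aug_rows.append({"path": str(new_path), "label": src["label"],
                             "split": "val", "origin": "augmented",
                             "seed": aug_seed})
    out = pd.concat([manifest, pd.DataFrame(aug_rows)], ignore_index=True)
    _validate_manifest(out)
    return out


def save_manifest(manifest: pd.DataFrame, path: str | Path):
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _validate_manifest(df)
    return df


def load_split_arrays(manifest: pd.DataFrame, split: str, input_side: int,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Load one split as standardized (N, 3, side, side) float32 + labels.

    Images are resized with bilinear interpolation and standardized with the
    fixed constants (mean 0.5, std 0.25 per channel).
    """
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"split {split!r} is empty")
    images, labels = [], []
    for _, row in rows.iterrows():
        img = iio.imread(row["path"]).astype(np.float64) / 255.0
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[0] != input_side:
            img = sktf.resize(img, (input_side, input_side), order=1,
                              anti_aliasing=img.shape[0] > input_side)
        images.append(((img - NORM_MEAN) / NORM_STD).transpose(2, 0, 1))
        labels.append(int(row["label"]))
    return np.asarray(images, dtype=np.float32), np.asarray(labels, dtype=np.int64)
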