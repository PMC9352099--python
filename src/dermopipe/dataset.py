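"""Dataset bookkeeping: photometric/geometric augmentation, stratified
splitting, k-fold partitioning and Gaussian-noise corruption.

A dataset is represented as a parallel pair (list of images, pandas index
table with ``path`` and ``label`` columns).  All counting logic also works
on the index alone, so bookkeeping at full-archive scale does not require
the pixels to exist in memory.

Brightness and contrast are both implemented as multiplicative factors
(brightness: gain on the raw intensities; contrast: gain on the deviations
about the image mean), with default factors 1.3 and 0.7 for the enhanced
and reduced variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AugmentParams",
    "SplitSpec",
    "FoldPlan",
    "NoiseParams",
    "adjust_brightness",
    "adjust_contrast",
    "variants_photometric",
    "variants_geometric",
    "augment_index",
    "augment_photometric",
    "augment_geometric",
    "split",
    "kfold",
    "add_noise",
]

PHOTOMETRIC_TAGS = ("bplus", "bminus", "cplus", "cminus")
GEOMETRIC_TAGS = ("hf", "vf", "r90", "r45")


@dataclass(frozen=True)
class AugmentParams:
    brightness_factors: tuple[float, float] = (1.3, 0.7)
    contrast_factors: tuple[float, float] = (1.3, 0.7)
    keep_original: bool = True

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.brightness_factors + self.contrast_factors):
            raise ValueError("augmentation factors must be > 0")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)  # train, val, test
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9 or any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive and sum to 1")


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: np.ndarray  # fold id per sample, aligned with the index
    seed: int


@dataclass(frozen=True)
class NoiseParams:
    kind: str = "gaussian"
    amount: float = 0.1  # variance on unit-scaled intensities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")
        if self.amount < 0:
            raise ValueError("amount must be >= 0")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness gain with clipping; factor > 1 brightens."""
    if factor <= 0:
        raise ValueError("brightness factor must be > 0")
    out = np.asarray(img, dtype=np.float64) * factor
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    """Gain on deviations about the image mean; factor > 1 widens contrast."""
    if factor <= 0:
        raise ValueError("contrast factor must be > 0")
    f = np.asarray(img, dtype=np.float64)
    mean = f.mean()
    out = mean + factor * (f - mean)
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def variants_photometric(img: np.ndarray, p: AugmentParams | None = None) -> dict[str, np.ndarray]:
    p = p or AugmentParams()
    b_hi, b_lo = p.brightness_factors
    c_hi, c_lo = p.contrast_factors
    return {
        "bplus": adjust_brightness(img, b_hi),
        "bminus": adjust_brightness(img, b_lo),
        "cplus": adjust_contrast(img, c_hi),
        "cminus": adjust_contrast(img, c_lo),
    }


def variants_geometric(img: np.ndarray) -> dict[str, np.ndarray]:
    """Horizontal/vertical flips and 90/45 degree rotations.

    The 45-degree rotation keeps the original canvas, filling exposed
    corners with black.
    """
    img = np.asarray(img)
    return {
        "hf": img[:, ::-1].copy(),
        "vf": img[::-1, :].copy(),
        "r90": np.rot90(img).copy(),
        "r45": ndimage.rotate(img, 45, axes=(1, 0), reshape=False, order=1, cval=0),
    }


def _tagged_path(path: str, tag: str) -> str:
    stem, dot, ext = path.rpartition(".")
    if not dot:
        return f"{path}_{tag}"
    return f"{stem}_{tag}.{ext}"


def augment_index(
    index: pd.DataFrame, p: AugmentParams | None = None, tags: tuple[str, ...] = PHOTOMETRIC_TAGS
) -> pd.DataFrame:
    """Expand the index table: original (optional) plus one row per variant."""
    p = p or AugmentParams()
    rows = []
    for _, row in index.iterrows():
        if p.keep_original:
            rows.append(dict(row))
        for tag in tags:
            r = dict(row)
            r["path"] = _tagged_path(str(row["path"]), tag)
            rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)


def augment_photometric(
    images: list[np.ndarray], index: pd.DataFrame, p: AugmentParams | None = None
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Original + four photometric variants per image (5x count); labels copied."""
    p = p or AugmentParams()
    out_imgs: list[np.ndarray] = []
    for img in images:
        if p.keep_original:
            out_imgs.append(np.asarray(img))
        var = variants_photometric(img, p)
        out_imgs.extend(var[t] for t in PHOTOMETRIC_TAGS)
    return out_imgs, augment_index(index, p, PHOTOMETRIC_TAGS)


def augment_geometric(
    images: list[np.ndarray], index: pd.DataFrame, keep_original: bool = True
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Original + four geometric variants per image (comparison harness)."""
    out_imgs: list[np.ndarray] = []
    for img in images:
        if keep_original:
            out_imgs.append(np.asarray(img))
        var = variants_geometric(img)
        out_imgs.extend(var[t] for t in GEOMETRIC_TAGS)
    p = AugmentParams(keep_original=keep_original)
    return out_imgs, augment_index(index, p, GEOMETRIC_TAGS)


def _class_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    # train rounded half-up, test rounded down, validation takes the remainder
    r_train, _, r_test = ratios
    n_train = int(np.floor(r_train * n + 0.5))
    n_test = int(np.floor(r_test * n))
    n_val = n - n_train - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split ratios produce a negative class allocation")
    return n_train, n_val, n_test


def split(index: pd.DataFrame, spec: SplitSpec | None = None) -> pd.DataFrame:
    """Stratified train/val/test split; adds a ``split`` column.

    Per class: the train count is the class size times the train ratio
    rounded half-up, the test count is rounded down, and validation takes
    the remainder.  Rows are shuffled deterministically under the seed.
    """
    spec = spec or SplitSpec()
    out = index.copy().reset_index(drop=True)
    out["split"] = ""
    rng = np.random.default_rng(spec.seed)
    groups = out.groupby("label").groups if spec.stratified else {"all": out.index}
    for _, idxs in sorted(groups.items()):
        idxs = np.asarray(idxs)
        if len(idxs) < 3:
            raise ValueError("each class needs at least 3 samples to split")
        perm = rng.permutation(len(idxs))
        shuffled = idxs[perm]
        n_train, n_val, n_test = _class_counts(len(idxs), spec.ratios)
        out.loc[shuffled[:n_train], "split"] = "train"
        out.loc[shuffled[n_train : n_train + n_val], "split"] = "val"
        out.loc[shuffled[n_train + n_val :], "split"] = "test"
    return out


def kfold(index: pd.DataFrame, k: int, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition; per-class fold sizes differ by at most 1."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    labels = index["label"].to_numpy()
    assignments = np.empty(len(index), dtype=np.int64)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(index)), labels)):
        assignments[val_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def add_noise(img: np.ndarray, p: NoiseParams | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise of variance ``amount`` on the unit scale.

    Pixels are scaled to [0, 1], corrupted, clipped and rescaled to 8 bits.
    ``amount`` = 0 is the identity.
    """
    p = p or NoiseParams()
    if p.amount == 0:
        return np.asarray(img).copy()
    rng = np.random.default_rng(p.seed)
    unit = np.asarray(img, dtype=np.float64) / 255.0
    noisy = unit + rng.normal(0.0, np.sqrt(p.amount), size=unit.shape)
    return np.clip(_round_half_away(np.clip(noisy, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
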