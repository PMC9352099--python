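"""Hair removal and contrast enhancement.

Thin dark structures (hairs, small vessels) narrower than the structuring
element are erased by grayscale morphological closing (dilation then
erosion with a flat kernel, applied per color channel); contrast is then
shaped by power-law (gamma) correction on unit-scaled intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "PreprocessConfig",
    "morphological_close",
    "gamma_correct",
    "preprocess",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: shape in {cross, rect, ellipse}, odd size (h, w)."""

    shape: str = "cross"
    size: tuple[int, int] = (15, 15)

    def footprint(self) -> np.ndarray:
        h, w = self.size
        if h < 1 or w < 1 or h % 2 == 0 or w % 2 == 0:
            raise ValueError("structuring element sides must be odd and >= 1")
        if self.shape == "rect":
            return np.ones((h, w), dtype=bool)
        if self.shape == "cross":
            fp = np.zeros((h, w), dtype=bool)
            fp[h // 2, :] = True
            fp[:, w // 2] = True
            return fp
        if self.shape == "ellipse":
            rr, cc = np.mgrid[0:h, 0:w]
            a, b = (h - 1) / 2 or 0.5, (w - 1) / 2 or 0.5
            return ((rr - (h - 1) / 2) / a) ** 2 + ((cc - (w - 1) / 2) / b) ** 2 <= 1.0
        raise ValueError(f"unknown structuring element shape: {self.shape!r}")


@dataclass(frozen=True)
class PreprocessConfig:
    closing_kernel: StructuringElement = field(default_factory=StructuringElement)
    gamma: float = 1.2

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def morphological_close(img: np.ndarray, kernel: StructuringElement | None = None) -> np.ndarray:
    """Grayscale closing (local max then local min), channel-wise for RGB.

    Borders are replicate-padded so image edges do not darken into spurious
    artifacts that would survive into segmentation.
    """
    if img.size == 0:
        raise ValueError("empty image")
    kernel = kernel or StructuringElement()
    fp = kernel.footprint()
    if fp.shape[0] > img.shape[0] or fp.shape[1] > img.shape[1]:
        raise ValueError("structuring element does not fit within the image")

    def _close_plane(plane: np.ndarray) -> np.ndarray:
        dil = ndimage.grey_dilation(plane, footprint=fp, mode="nearest")
        return ndimage.grey_erosion(dil, footprint=fp, mode="nearest")

    if img.ndim == 2:
        return _close_plane(img)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = _close_plane(img[..., c])
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law transform: out = round(255 * (v/255)**gamma) per channel.

    gamma < 1 brightens, gamma > 1 darkens; 0 and 255 are fixed points.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    scaled = np.asarray(img, dtype=np.float64) / 255.0
    out = 255.0 * np.power(scaled, gamma)
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Closing followed by gamma correction (the hair-removal -> enhancement chain)."""
    cfg = cfg or PreprocessConfig()
    return gamma_correct(morphological_close(img, cfg.closing_kernel), cfg.gamma)
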