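"""Lesion ROI extraction via the five-stage mask pipeline.

The chain is: grayscale conversion -> Otsu binarization (mask-1, polarity
normalized so the lesion is the white foreground) -> 5x5 dilation (mask-2)
-> pixel subtraction mask-2 minus mask-1, leaving a thin edge ring (mask-3)
-> largest-blob selection on the ring (mask-4) -> hole filling (final mask)
-> bitwise conjunction with the preprocessed image (ROI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "OtsuResult",
    "SegmentationResult",
    "to_grayscale",
    "otsu_threshold",
    "dilate_mask",
    "subtract_masks",
    "largest_blob",
    "fill_holes",
    "apply_mask",
    "segment",
]

# Manual fallback threshold for the non-automatic mode; the automatic Otsu
# threshold supersedes it whenever it is enabled (the default).
MANUAL_THRESHOLD = 120


@dataclass(frozen=True)
class OtsuResult:
    threshold: int
    between_class_variance: float
    class_means: tuple[float, float]
    class_weights: tuple[float, float]
    mask: np.ndarray  # uint8 {0, 255}; 255 where intensity > threshold


@dataclass(frozen=True)
class SegmentationResult:
    mask1: np.ndarray | None  # Otsu, polarity-normalized
    mask2: np.ndarray | None  # dilated
    mask3: np.ndarray | None  # subtraction (edge ring)
    mask4: np.ndarray | None  # largest blob of the ring
    final_mask: np.ndarray | None  # hole-filled
    roi: np.ndarray | None  # masked image
    otsu: OtsuResult | None = None
    diagnostic: str | None = None


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Standard luminance weighting 0.299 R + 0.587 G + 0.114 B, rounded to uint8."""
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    f = img.astype(np.float64)
    gray = 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> OtsuResult:
    """Threshold maximizing the between-class variance w0*w1*(mu0-mu1)^2.

    Every candidate t in [0, 255] is scanned; class 0 holds intensities <= t,
    class 1 holds intensities > t.  The returned mask marks intensities
    strictly above the threshold as white (255).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("otsu_threshold expects a grayscale image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate input: image has fewer than 2 distinct levels")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / n  # weight of class <= t
    w1 = 1.0 - w0
    cum = np.cumsum(hist * levels)
    total = cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum / np.cumsum(hist)
        mu1 = (total - cum) / (n - np.cumsum(hist))
    sigma2 = w0 * w1 * (mu0 - mu1) ** 2
    sigma2 = np.nan_to_num(sigma2, nan=0.0)
    t = int(np.argmax(sigma2))
    mask = np.where(img > t, 255, 0).astype(np.uint8)
    return OtsuResult(
        threshold=t,
        between_class_variance=float(sigma2[t]),
        class_means=(float(mu0[t]), float(np.nan_to_num(mu1[t]))),
        class_weights=(float(w0[t]), float(w1[t])),
        mask=mask,
    )


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 255)).all():
        raise ValueError("mask must contain only values {0, 255}")
    return mask


def dilate_mask(mask: np.ndarray, kernel_size: tuple[int, int] = (5, 5)) -> np.ndarray:
    """Binary set dilation with a rectangular kernel; output superset of input."""
    mask = _check_binary(mask)
    fp = np.ones(kernel_size, dtype=bool)
    out = ndimage.binary_dilation(mask > 0, structure=fp)
    return np.where(out, 255, 0).astype(np.uint8)


def subtract_masks(mask2: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Pixelwise subtraction of mask-1 from mask-2.

    Defined for mask2 a dilation of mask1: white where mask2 is white and
    mask1 is black, black elsewhere.  A pixel with mask2 black but mask1
    white violates that contract; it is reported and set to black.
    """
    mask2, mask1 = _check_binary(mask2), _check_binary(mask1)
    if mask2.shape != mask1.shape:
        raise ValueError("mask shapes differ")
    violation = (mask2 == 0) & (mask1 == 255)
    if violation.any():
        warnings.warn(
            f"subtract_masks: {int(violation.sum())} pixels have mask2=0, mask1=255 "
            "(undefined case); set to 0",
            stacklevel=2,
        )
    return np.where((mask2 == 255) & (mask1 == 0), 255, 0).astype(np.uint8)


def largest_blob(mask: np.ndarray) -> np.ndarray:
    """Keep only the connected component with the largest enclosed (filled) area.

    Components are 8-connected; area is the pixel count of the hole-filled
    component, so a thin edge ring is ranked by the region it encloses.  Ties
    break toward the component found first in scan order.
    """
    mask = _check_binary(mask)
    labels, n = ndimage.label(mask > 0, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise ValueError("largest_blob: mask has no white pixels")
    best_label, best_area = 1, -1
    for lab in range(1, n + 1):
        area = int(ndimage.binary_fill_holes(labels == lab).sum())
        if area > best_area:
            best_label, best_area = lab, area
    return np.where(labels == best_label, 255, 0).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes: background not reachable from the border becomes white."""
    mask = _check_binary(mask)
    filled = ndimage.binary_fill_holes(mask > 0)
    return np.where(filled, 255, 0).astype(np.uint8)


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bitwise conjunction: keep image pixels where the mask is white, zero elsewhere."""
    mask = _check_binary(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    keep = mask == 255
    if img.ndim == 3:
        keep = keep[..., None]
    return np.where(keep, img, 0).astype(img.dtype)


def _normalize_polarity(mask: np.ndarray) -> np.ndarray:
    # the lesion is darker and smaller than the surrounding skin, so when the
    # white fraction exceeds half the white class is skin -> invert
    if (mask == 255).mean() > 0.5:
        return (255 - mask).astype(np.uint8)
    return mask


def segment(img: np.ndarray, dilation_kernel: tuple[int, int] = (5, 5)) -> SegmentationResult:
    """Run the full mask chain on a preprocessed image, keeping intermediates."""
    gray = to_grayscale(img)
    try:
        otsu = otsu_threshold(gray)
    except ValueError as exc:
        return SegmentationResult(None, None, None, None, None, None, None, str(exc))
    mask1 = _normalize_polarity(otsu.mask)
    if not (mask1 == 255).any():
        return SegmentationResult(
            mask1, None, None, None, None, None, otsu, "empty foreground after thresholding"
        )
    mask2 = dilate_mask(mask1, dilation_kernel)
    mask3 = subtract_masks(mask2, mask1)
    if not (mask3 == 255).any():
        return SegmentationResult(
            mask1, mask2, mask3, None, None, None, otsu, "empty edge ring after subtraction"
        )
    mask4 = largest_blob(mask3)
    final = fill_holes(mask4)
    roi = apply_mask(img, final)
    return SegmentationResult(mask1, mask2, mask3, mask4, final, roi, otsu, None)
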