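"""Image-pair fidelity metrics: MSE, PSNR, RMSE, SSIM, DSC and histograms.

RGB pairs are converted to luminance before MSE/PSNR/SSIM.  PSNR uses the
standard 10*log10(MAX^2 / MSE) with MAX = 255.  DSC operates on binary
masks; for photographs both images are binarized at mid-intensity (128)
first.  SSIM uses the conventional 11x11 Gaussian window with sigma 1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .segment import to_grayscale

__all__ = [
    "QualityReport",
    "HistogramPair",
    "mse",
    "psnr",
    "rmse_pair",
    "ssim",
    "dsc",
    "binarize",
    "histogram_compare",
    "quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    mse: float
    psnr: float  # dB; +inf for identical images
    ssim: float
    rmse: float
    dsc: float


@dataclass(frozen=True)
class HistogramPair:
    bins_x: np.ndarray  # 256 counts
    bins_y: np.ndarray
    l1_distance: int


def _as_gray_pair(g: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g, p = np.asarray(g), np.asarray(p)
    if g.shape[:2] != p.shape[:2]:
        raise ValueError("image dimensions differ")
    return to_grayscale(g), to_grayscale(p)


def mse(g: np.ndarray, p: np.ndarray) -> float:
    """Mean squared pixel error (on luminance for RGB pairs)."""
    gg, pp = _as_gray_pair(g, p)
    diff = gg.astype(np.float64) - pp.astype(np.float64)
    return float(np.mean(diff**2))


def psnr(g: np.ndarray, p: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    m = mse(g, p)
    if m == 0:
        return math.inf
    return float(10.0 * math.log10(max_value**2 / m))


def rmse_pair(g: np.ndarray, p: np.ndarray) -> float:
    return math.sqrt(mse(g, p))


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Mean structural similarity over a Gaussian-weighted local window."""
    gx, gy = _as_gray_pair(x, y)
    if min(gx.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            gx,
            gy,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=255,
            K1=0.01,
            K2=0.03,
        )
    )


def binarize(img: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Mid-intensity binarization used when DSC is applied to photographs."""
    gray = to_grayscale(np.asarray(img))
    return np.where(gray >= threshold, 255, 0).astype(np.uint8)


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A^B| / (|A|+|B|) of two binary masks.

    Two empty masks agree perfectly and give 1.0.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("mask dimensions differ")
    fa, fb = a > 0, b > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((fa & fb).sum()) / denom


def histogram_compare(x: np.ndarray, y: np.ndarray) -> HistogramPair:
    """256-bin intensity histograms of both images plus their L1 distance."""
    gx, gy = to_grayscale(np.asarray(x)), to_grayscale(np.asarray(y))
    hx = np.bincount(gx.ravel(), minlength=256)
    hy = np.bincount(gy.ravel(), minlength=256)
    return HistogramPair(bins_x=hx, bins_y=hy, l1_distance=int(np.abs(hx - hy).sum()))


def quality_report(before: np.ndarray, after: np.ndarray) -> QualityReport:
    """All five metrics for one image pair (one table row)."""
    m = mse(before, after)
    return QualityReport(
        mse=m,
        psnr=psnr(before, after),
        ssim=ssim(before, after),
        rmse=math.sqrt(m),
        dsc=dsc(binarize(before), binarize(after)),
    )
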