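"""Byte-size reduction by smoothing ("down-scaling").

Here down-scaling means shrinking the *stored* size of an image without
touching its pixel dimensions: an edge-preserving bilateral filter removes
noise, then a uniform box blur flattens what remains, and the smoother
result compresses to fewer bytes under the same codec.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "BilateralParams",
    "BoxBlurParams",
    "SizeReport",
    "bilateral_filter",
    "box_blur",
    "box_blur_four_pixel",
    "downscale",
    "size_report",
]


@dataclass(frozen=True)
class BilateralParams:
    diameter: int = 5  # neighborhood footprint (d x d)
    sigma_color: float = 75.0  # range sigma (intensity units)
    sigma_space: float = 75.0  # spatial sigma (pixels)

    def __post_init__(self) -> None:
        if self.diameter < 1 or self.diameter % 2 == 0:
            raise ValueError("diameter must be odd and >= 1")
        if self.sigma_color <= 0 or self.sigma_space <= 0:
            raise ValueError("sigmas must be > 0")


@dataclass(frozen=True)
class BoxBlurParams:
    radius: int = 2  # window is (2r+1) x (2r+1)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class SizeReport:
    bytes_before: int
    bytes_after: int
    codec: str

    @property
    def reduction_ratio(self) -> float:
        return self.bytes_after / self.bytes_before


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _pad_edge(plane: np.ndarray, r: int) -> np.ndarray:
    return np.pad(plane, r, mode="edge")


def _bilateral_plane(plane: np.ndarray, p: BilateralParams) -> np.ndarray:
    r = p.diameter // 2
    padded = _pad_edge(plane, r)
    h, w = plane.shape
    num = np.zeros((h, w), dtype=np.float64)
    den = np.zeros((h, w), dtype=np.float64)
    inv2sd = 1.0 / (2.0 * p.sigma_space**2)
    inv2sr = 1.0 / (2.0 * p.sigma_color**2)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            shifted = padded[r + dr : r + dr + h, r + dc : r + dc + w]
            w_spatial = np.exp(-(dr * dr + dc * dc) * inv2sd)
            w_range = np.exp(-((shifted - plane) ** 2) * inv2sr)
            wgt = w_spatial * w_range
            num += wgt * shifted
            den += wgt
    return num / den


def bilateral_filter(img: np.ndarray, p: BilateralParams | None = None) -> np.ndarray:
    """Edge-preserving smoother: each output pixel is a weighted mean of its
    d-neighborhood, weights decaying with both spatial and intensity distance
    (Gaussian in each).  Applied per channel; dimensions unchanged."""
    p = p or BilateralParams()
    f = np.asarray(img, dtype=np.float64)
    if f.ndim == 2:
        out = _bilateral_plane(f, p)
    else:
        out = np.stack([_bilateral_plane(f[..., c], p) for c in range(f.shape[2])], axis=-1)
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def _box_plane(plane: np.ndarray, r: int) -> np.ndarray:
    padded = _pad_edge(plane, r)
    h, w = plane.shape
    acc = np.zeros((h, w), dtype=np.float64)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            acc += padded[r + dr : r + dr + h, r + dc : r + dc + w]
    return acc / (2 * r + 1) ** 2


def box_blur(img: np.ndarray, p: BoxBlurParams | None = None) -> np.ndarray:
    """Uniform moving average over a (2r+1)x(2r+1) window, replicate-padded.

    r = 0 is the identity.  Accumulation is in float64 and rounded
    half-away-from-zero back to 8 bits.
    """
    p = p or BoxBlurParams()
    if p.radius == 0:
        return np.asarray(img).copy()
    f = np.asarray(img, dtype=np.float64)
    if f.ndim == 2:
        out = _box_plane(f, p.radius)
    else:
        out = np.stack([_box_plane(f[..., c], p.radius) for c in range(f.shape[2])], axis=-1)
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def box_blur_four_pixel(img: np.ndarray) -> np.ndarray:
    """Literal four-pixel variant: each output pixel is the mean of the 2x2
    block anchored at it (documented alternative to the symmetric window)."""
    f = np.asarray(img, dtype=np.float64)
    padded = np.pad(f, [(0, 1), (0, 1)] + [(0, 0)] * (f.ndim - 2), mode="edge")
    out = (
        padded[:-1, :-1] + padded[:-1, 1:] + padded[1:, :-1] + padded[1:, 1:]
    ) / 4.0
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def downscale(
    img: np.ndarray,
    bp: BilateralParams | None = None,
    xp: BoxBlurParams | None = None,
) -> np.ndarray:
    """Bilateral filter followed by box blur."""
    return box_blur(bilateral_filter(img, bp), xp)


def _encode(img: np.ndarray, codec: str) -> int:
    buf = io.BytesIO()
    pil = Image.fromarray(np.asarray(img))
    if codec == "png":
        pil.save(buf, format="PNG")
    elif codec == "jpeg":
        pil.save(buf, format="JPEG", quality=85)
    else:
        raise ValueError(f"unknown codec: {codec!r}")
    return buf.getbuffer().nbytes


def size_report(img_before: np.ndarray, img_after: np.ndarray, codec: str = "png") -> SizeReport:
    """Encode both images with the same codec and report the byte counts.

    PNG (lossless) is the default so the ratio reflects information content;
    JPEG quality 85 is available as a lossy alternative.
    """
    return SizeReport(
        bytes_before=_encode(img_before, codec),
        bytes_after=_encode(img_after, codec),
        codec=codec,
    )
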