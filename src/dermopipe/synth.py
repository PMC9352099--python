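"""Synthetic dermoscopy-style image generator with ground-truth lesion masks.

Real dermoscopy frames show a skin-toned background, a darker irregular
lesion, dark hair strokes crossing the field of view and small bright air
bubbles.  This module emulates those four ingredients well enough that every
downstream stage (hair removal, segmentation, down-scaling, classification)
can be exercised against a known ground truth without any external data.

The lesion is a filled ellipse whose boundary radius is perturbed by a
smooth periodic function (a few random Fourier harmonics), which gives the
irregular, lobed borders typical of melanocytic lesions.  The ground-truth
mask is recorded *before* hairs and bubbles are painted, so artifacts may
cross the lesion without altering the truth - exactly the situation the
preprocessing stage has to cope with.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = [
    "LesionParams",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "save_dataset",
    "BENIGN_STYLE",
    "MALIGNANT_STYLE",
]


@dataclass(frozen=True)
class LesionParams:
    """Parameters of one synthetic dermoscopy sample.

    All coordinates are 0-based ``(row, col)``, row-major.  Colors are RGB
    triples in 0-255.
    """

    image_side: int = 224
    skin_base: tuple[int, int, int] = (224, 172, 148)
    skin_noise_sd: float = 6.0
    lesion_center: tuple[int, int] = (112, 112)
    lesion_axes: tuple[int, int] = (55, 42)
    lesion_angle: float = 0.0
    lesion_color: tuple[int, int, int] = (120, 78, 60)
    border_jitter: float = 0.15
    n_hairs: int = 6
    hair_width: int = 2
    hair_color: tuple[int, int, int] = (38, 28, 22)
    n_bubbles: int = 4
    seed: int = 0

    def validate(self) -> None:
        a, b = self.lesion_axes
        if min(a, b) < 4:
            raise ValueError("lesion axes must be >= 4 px")
        if not 0.0 <= self.border_jitter < 0.5:
            raise ValueError("border_jitter must lie in [0, 0.5)")
        if self.image_side < 8:
            raise ValueError("image_side too small")
        # worst-case boundary radius must keep the ellipse inside the frame
        reach = max(a, b) * (1.0 + self.border_jitter)
        r, c = self.lesion_center
        side = self.image_side
        if r - reach < 0 or c - reach < 0 or r + reach > side - 1 or c + reach > side - 1:
            raise ValueError("lesion ellipse (including border jitter) exceeds image bounds")


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) uint8, values {0, 255}
    label: str  # "benign" | "malignant"
    params: LesionParams


def _lesion_mask(p: LesionParams, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of the radially-jittered filled ellipse.

    With ``border_jitter == 0`` this reduces to the exact discrete ellipse
    inequality (x'/a)^2 + (y'/b)^2 <= 1.
    """
    side = p.image_side
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    dr = rr - p.lesion_center[0]
    dc = cc - p.lesion_center[1]
    theta = np.deg2rad(p.lesion_angle)
    # rotate into the ellipse frame
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    a, b = p.lesion_axes
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1.0 on the unperturbed boundary
    if p.border_jitter > 0:
        phi = np.arctan2(v, u)
        harmonics = rng.integers(2, 7, size=3)
        amps = rng.uniform(0.3, 1.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        wave = np.zeros_like(phi)
        for h, amp, ph in zip(harmonics, amps, phases):
            wave += amp * np.sin(h * phi + ph)
        wave /= np.abs(wave).max() + 1e-12
        boundary = 1.0 + p.border_jitter * wave
    else:
        boundary = 1.0
    return rho <= boundary


def _draw_hairs(img: Image.Image, p: LesionParams, rng: np.random.Generator) -> None:
    side = p.image_side
    draw = ImageDraw.Draw(img)
    for _ in range(p.n_hairs):
        # endpoints on opposite borders, one bowed control point -> curved stroke
        edge = rng.integers(0, 2)
        if edge == 0:  # left-right
            x0, y0 = -5.0, float(rng.uniform(0, side))
            x1, y1 = side + 5.0, float(rng.uniform(0, side))
        else:  # top-bottom
            x0, y0 = float(rng.uniform(0, side)), -5.0
            x1, y1 = float(rng.uniform(0, side)), side + 5.0
        cx = (x0 + x1) / 2 + float(rng.uniform(-side / 3, side / 3))
        cy = (y0 + y1) / 2 + float(rng.uniform(-side / 3, side / 3))
        t = np.linspace(0.0, 1.0, 64)
        bx = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * cx + t**2 * x1
        by = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * cy + t**2 * y1
        draw.line(list(zip(bx.tolist(), by.tolist())), fill=tuple(p.hair_color), width=p.hair_width)


def _draw_bubbles(img: Image.Image, p: LesionParams, rng: np.random.Generator) -> None:
    side = p.image_side
    draw = ImageDraw.Draw(img)
    for _ in range(p.n_bubbles):
        r = float(rng.uniform(2, 5))
        x = float(rng.uniform(r, side - r))
        y = float(rng.uniform(r, side - r))
        draw.ellipse([x - r, y - r, x + r, y + r], fill=(250, 248, 245))


def generate_sample(params: LesionParams, label: str = "benign") -> SyntheticSample:
    """Render one sample; deterministic for a fixed ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    side = params.image_side

    skin = np.empty((side, side, 3), dtype=np.float64)
    skin[...] = np.asarray(params.skin_base, dtype=np.float64)
    if params.skin_noise_sd > 0:
        skin += rng.normal(0.0, params.skin_noise_sd, size=skin.shape)

    mask = _lesion_mask(params, rng)

    lesion = np.empty_like(skin)
    lesion[...] = np.asarray(params.lesion_color, dtype=np.float64)
    if params.skin_noise_sd > 0:
        lesion += rng.normal(0.0, params.skin_noise_sd, size=lesion.shape)

    canvas = np.where(mask[..., None], lesion, skin)
    canvas = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    # truth recorded now: hairs/bubbles may overpaint the lesion afterwards
    truth = np.where(mask, 255, 0).astype(np.uint8)

    pil = Image.fromarray(canvas)
    if params.n_hairs > 0:
        _draw_hairs(pil, params, rng)
    if params.n_bubbles > 0:
        _draw_bubbles(pil, params, rng)
    return SyntheticSample(image=np.asarray(pil), truth_mask=truth, label=label, params=params)


# Class styles: benign lesions are rendered lighter and smoother, malignant
# darker with more irregular borders, mirroring the clinical tendency that
# separates the classes.  Each entry is (low, high) for uniform sampling.
BENIGN_STYLE: dict[str, tuple] = {
    "lesion_color": ((150, 105, 85), (180, 135, 110)),
    "border_jitter": (0.03, 0.10),
    "axes": (0.134, 0.246),  # fraction of the image side
}
MALIGNANT_STYLE: dict[str, tuple] = {
    "lesion_color": ((60, 35, 25), (110, 70, 55)),
    "border_jitter": (0.18, 0.32),
    "axes": (0.156, 0.277),
}

_DEFAULT_STYLES = {"benign": BENIGN_STYLE, "malignant": MALIGNANT_STYLE}


def _sample_params(style: dict, side: int, seed: int, rng: np.random.Generator) -> LesionParams:
    lo, hi = style["lesion_color"]
    color = tuple(int(rng.integers(l, h + 1)) for l, h in zip(lo, hi))
    jitter = float(rng.uniform(*style["border_jitter"]))
    ax_lo = max(4, int(round(style["axes"][0] * side)))
    ax_hi = max(ax_lo, int(round(style["axes"][1] * side)))
    a = int(rng.integers(ax_lo, ax_hi + 1))
    b = int(rng.integers(ax_lo, ax_hi + 1))
    reach = max(a, b) * (1 + jitter) + 2
    center = (
        int(rng.integers(int(np.ceil(reach)), side - int(np.ceil(reach)))),
        int(rng.integers(int(np.ceil(reach)), side - int(np.ceil(reach)))),
    )
    return LesionParams(
        image_side=side,
        lesion_center=center,
        lesion_axes=(a, b),
        lesion_angle=float(rng.uniform(0, 180)),
        lesion_color=color,
        border_jitter=jitter,
        seed=seed,
    )


def generate_dataset(
    n_per_class: int,
    class_styles: dict[str, dict] | None = None,
    seed: int = 0,
    image_side: int = 224,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate ``n_per_class`` samples per class plus an index table.

    Every sample draws its own seeded random stream from
    ``(dataset seed, sample index)``, so regenerating the dataset (or any
    single sample) is reproducible and order-independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    styles = class_styles or _DEFAULT_STYLES
    samples: list[SyntheticSample] = []
    rows = []
    idx = 0
    for label in sorted(styles):
        style = styles[label]
        for _ in range(n_per_class):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            child_seed = int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            rng = np.random.default_rng(child_seed)
            params = _sample_params(style, image_side, child_seed, rng)
            samples.append(generate_sample(params, label=label))
            rows.append({"path": f"{label}_{idx:05d}.png", "label": label, "split": ""})
            idx += 1
    return samples, pd.DataFrame(rows)


def save_dataset(samples: list[SyntheticSample], index: pd.DataFrame, outdir: str | Path) -> Path:
    """Write PNG images + masks, the CSV index and a JSON params sidecar."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for sample, path in zip(samples, index["path"]):
        Image.fromarray(sample.image).save(outdir / "images" / path)
        Image.fromarray(sample.truth_mask).save(outdir / "masks" / path)
        sidecar[path] = dataclasses.asdict(sample.params)
    index.to_csv(outdir / "index.csv", index=False)
    (outdir / "params.json").write_text(json.dumps(sidecar, indent=1))
    return outdir
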