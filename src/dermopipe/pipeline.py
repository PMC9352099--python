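"""End-to-end orchestration: synthetic data -> preprocessing -> segmentation
-> down-scaling + quality report -> augmentation -> split -> training ->
evaluation, with every stage's artifacts written to disk and a summary JSON.

``RunConfig`` holds one flat block of parameters whose defaults are the
pipeline's operating point (gamma 1.2, cross 15x15 closing, 5x5 dilation,
bilateral d=5 / sigma 75/75, box-blur radius 2, factors 1.3/0.7, 70:20:10
split, Adam 0.001, batch 32).  The demo profile shrinks the image side,
sample count and epochs so the full chain runs in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import dataset as ds
from . import downscale as dsc_mod
from . import evalmetrics, quality, scnn, segment, synth
from .preprocess import PreprocessConfig, StructuringElement, preprocess

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "info"
    # synth
    n_per_class: int = 10
    image_side: int = 224
    # preprocess
    closing_shape: str = "cross"
    closing_size: int = 15
    gamma: float = 1.2
    # segment
    dilation_kernel: int = 5
    run_segment: bool = True
    # downscale
    run_downscale: bool = True
    bilateral_diameter: int = 5
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0
    boxblur_radius: int = 2
    # augmentation
    factor_hi: float = 1.3
    factor_lo: float = 0.7
    # split
    ratio_train: float = 0.7
    ratio_val: float = 0.2
    ratio_test: float = 0.1
    # training
    run_train: bool = True
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 200
    loss: str = "categorical_ce"
    output_activation: str = "softmax"

    @staticmethod
    def demo() -> "RunConfig":
        return RunConfig(n_per_class=10, image_side=64, epochs=4, batch_size=16)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _save_images(images, names, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for img, name in zip(images, names):
        Image.fromarray(np.asarray(img)).save(outdir / name)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every enabled stage in order; returns (and writes) the summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # 1. synthetic data with ground truth
    samples, index = synth.generate_dataset(cfg.n_per_class, seed=cfg.seed, image_side=cfg.image_side)
    synth.save_dataset(samples, index, out / "raw")
    summary["n_samples"] = len(samples)

    # 2. preprocessing: closing (hair removal) + gamma (enhancement)
    pre_cfg = PreprocessConfig(
        closing_kernel=StructuringElement(cfg.closing_shape, (cfg.closing_size, cfg.closing_size)),
        gamma=cfg.gamma,
    )
    pre_images = [preprocess(s.image, pre_cfg) for s in samples]
    _save_images(pre_images, index["path"], out / "preprocessed")

    # 3. segmentation against ground truth
    if cfg.run_segment:
        dices, thresholds = [], []
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for s, img, name in zip(samples, pre_images, index["path"]):
            res = segment.segment(img, (cfg.dilation_kernel, cfg.dilation_kernel))
            if res.final_mask is not None:
                dices.append(quality.dsc(res.final_mask, s.truth_mask))
                thresholds.append(res.otsu.threshold)
                Image.fromarray(res.final_mask).save(out / "masks" / name)
        summary["segmentation"] = {
            "median_dsc": float(np.median(dices)) if dices else None,
            "otsu_thresholds": thresholds,
        }

    # 4. down-scaling + quality metrics
    work_images = pre_images
    if cfg.run_downscale:
        bp = dsc_mod.BilateralParams(
            cfg.bilateral_diameter, cfg.bilateral_sigma_color, cfg.bilateral_sigma_space
        )
        xp = dsc_mod.BoxBlurParams(cfg.boxblur_radius)
        down_images = [dsc_mod.downscale(img, bp, xp) for img in pre_images]
        _save_images(down_images, index["path"], out / "downscaled")
        rows = []
        for name, before, after in zip(index["path"], pre_images, down_images):
            rep = quality.quality_report(before, after)
            size = dsc_mod.size_report(before, after)
            rows.append(
                {
                    "image": name,
                    "mse": rep.mse,
                    "psnr": rep.psnr,
                    "ssim": rep.ssim,
                    "rmse": rep.rmse,
                    "dsc": rep.dsc,
                    "bytes_before": size.bytes_before,
                    "bytes_after": size.bytes_after,
                }
            )
        qtable = pd.DataFrame(rows)
        qtable.to_csv(out / "quality.csv", index=False)
        summary["downscale"] = {
            "mean_ssim": float(qtable["ssim"].mean()),
            "mean_psnr": float(qtable["psnr"][np.isfinite(qtable["psnr"])].mean()),
            "mean_size_ratio": float((qtable["bytes_after"] / qtable["bytes_before"]).mean()),
        }
        work_images = down_images

    # 5. photometric augmentation (5x)
    aug_params = ds.AugmentParams((cfg.factor_hi, cfg.factor_lo), (cfg.factor_hi, cfg.factor_lo))
    aug_images, aug_index = ds.augment_photometric(work_images, index, aug_params)
    summary["n_augmented"] = len(aug_images)

    # 6. stratified split
    spec = ds.SplitSpec((cfg.ratio_train, cfg.ratio_val, cfg.ratio_test), seed=cfg.seed)
    aug_index = ds.split(aug_index, spec)
    aug_index.to_csv(out / "index.csv", index=False)
    summary["split_counts"] = aug_index["split"].value_counts().to_dict()

    # 7. training + evaluation on the split
    if cfg.run_train:
        labels = (aug_index["label"] == "malignant").astype(int).to_numpy()
        x = np.stack(aug_images)
        masks = {name: aug_index["split"].to_numpy() == name for name in ("train", "val", "test")}
        side = cfg.image_side
        model_spec = scnn.ModelSpec(
            input_shape=(side, side, 3),
            conv_filters=(4, 8, 8, 16) if side <= 96 else (16, 32, 32, 64),
            dense_units=256 if side <= 96 else 1024,
            output_activation=cfg.output_activation,
        )
        train_cfg = scnn.TrainConfig(
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            loss=cfg.loss,
            output_activation=cfg.output_activation,
            seed=cfg.seed,
        )
        model = scnn.build_model(model_spec, seed=cfg.seed)
        model = scnn.train(
            model, x[masks["train"]], labels[masks["train"]], x[masks["val"]], labels[masks["val"]], train_cfg
        )
        pd.DataFrame(model.history).to_csv(out / "training_log.csv", index=False)
        _, pred = scnn.predict(model, x[masks["test"]])
        cm = evalmetrics.confusion(labels[masks["test"]], pred)
        report = evalmetrics.metrics(cm)
        summary["evaluation"] = {
            "confusion": dataclasses.asdict(cm),
            **{k: (v if np.isfinite(v) else None) for k, v in dataclasses.asdict(report).items()},
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
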