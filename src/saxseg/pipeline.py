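"""End-to-end pipeline stages with config, seeding, and manifests.

One global seed fans out to fixed per-stage offsets (phantom +0, network
init +1000, training shuffle +2000) so any stage can be re-run in
isolation and reproduce the same artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conversion import convert_directory, load_slice_pair, save_slice_pair
from .metrics import MetricAccumulator
from .nn.network import (
    build_network,
    default_network_spec,
    load_network,
    predict_mask,
    save_network,
)
from .phantom import LabeledSlice, PhantomParams, generate_dataset
from .training import TrainConfig, train
from .weighting import ClassWeights, compute_class_weights

__all__ = ["RunConfig", "run_pipeline", "overlay_mask", "STAGES"]

STAGES = ("phantom", "convert", "weights", "train", "evaluate", "predict")

PHANTOM_SEED_OFFSET = 0
NETWORK_SEED_OFFSET = 1000
TRAIN_SEED_OFFSET = 2000


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    in_dir: str | None = None  # NIfTI source for the convert stage
    predict_image: str | None = None
    seed: int = 0
    n_slices: int = 100
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    height: int = 256
    width: int = 192
    num_classes: int = 3
    phantom: dict = field(default_factory=dict)  # PhantomParams overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    bf_tolerance: float | None = None

    def phantom_params(self) -> PhantomParams:
        return PhantomParams(height=self.height, width=self.width, **self.phantom)

    def train_config(self) -> TrainConfig:
        overrides = dict(self.train)
        overrides.setdefault("seed", self.seed + TRAIN_SEED_OFFSET)
        return TrainConfig(**overrides)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        if "split" in doc:
            doc["split"] = tuple(doc["split"])
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _log_stage(out: Path, stage: str, config: RunConfig, outputs: list[str]) -> None:
    line = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }
    with (out / "manifest.jsonl").open("a") as fh:
        fh.write(json.dumps(line) + "\n")


def _load_split(out: Path, split: str) -> list[LabeledSlice]:
    data = out / "data"
    manifest = pd.read_csv(data / "manifest.csv")
    if "split" in manifest.columns:
        manifest = manifest[manifest["split"] == split]
    slices = []
    for _, row in manifest.iterrows():
        stem = f"{row['patient_id']}_s{int(row['slice_index']):03d}.png"
        slices.append(load_slice_pair(data / "images" / stem, data / "masks" / stem))
    return slices


def _stage_phantom(config: RunConfig, out: Path) -> list[str]:
    ds = generate_dataset(
        config.n_slices,
        config.phantom_params(),
        seed=config.seed + PHANTOM_SEED_OFFSET,
        split=config.split,
    )
    data = out / "data"
    for name in ("train", "val", "test"):
        for slc in ds[name]:
            save_slice_pair(slc, data)
    ds["manifest"].to_csv(data / "manifest.csv", index=False)
    return [str(data / "manifest.csv")]


def _stage_convert(config: RunConfig, out: Path) -> list[str]:
    if not config.in_dir:
        raise ValueError("convert stage needs in_dir pointing at NIfTI volumes")
    convert_directory(config.in_dir, out / "data", target=(config.height, config.width))
    return [str(out / "data" / "manifest.csv")]


def _stage_weights(config: RunConfig, out: Path) -> list[str]:
    slices = _load_split(out, "train")
    if not slices:
        raise ValueError("no training slices found; run the phantom or convert stage first")
    cw = compute_class_weights((s.mask for s in slices), config.num_classes)
    path = out / "weights.json"
    path.write_text(json.dumps(cw.to_dict(), indent=2))
    return [str(path)]


def _load_weights(config: RunConfig, out: Path) -> ClassWeights:
    path = out / "weights.json"
    if not path.exists():
        raise FileNotFoundError("weights.json missing; run the weights stage first")
    doc = json.loads(path.read_text())
    return ClassWeights(
        weights=np.asarray(doc["weights"]),
        frequencies=np.asarray(doc["frequencies"]),
        total_pixels=doc.get("total_pixels", 0),
    )


def _stage_train(config: RunConfig, out: Path) -> list[str]:
    slices = _load_split(out, "train")
    if not slices:
        raise ValueError("no training slices found; run the phantom or convert stage first")
    weights = _load_weights(config, out)
    spec = default_network_spec(
        num_classes=config.num_classes, input_shape=(config.height, config.width, 1)
    )
    net = build_network(spec, seed=config.seed + NETWORK_SEED_OFFSET)
    net, history = train(net, slices, config.train_config(), weights=weights)
    ckpt = out / "checkpoint.npz"
    save_network(net, ckpt)
    history.to_frame().to_csv(out / "history.csv", index=False)
    return [str(ckpt), str(out / "history.csv")]


def _stage_evaluate(config: RunConfig, out: Path) -> list[str]:
    ckpt = out / "checkpoint.npz"
    if not ckpt.exists():
        raise FileNotFoundError("checkpoint.npz missing; run the train stage first")
    net = load_network(ckpt)
    slices = _load_split(out, "test")
    if not slices:
        raise ValueError("no test slices found; run the phantom or convert stage first")
    acc = MetricAccumulator(config.num_classes, tolerance=config.bf_tolerance)
    for s in slices:
        acc.add(predict_mask(net, s.image), np.asarray(s.mask))
    report = acc.report()
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.to_frame().to_csv(out / "metrics.csv", index=True)
    acc.cm.to_frame().to_csv(out / "confusion.csv")
    return [str(out / "metrics.json"), str(out / "confusion.csv")]


def overlay_mask(image: np.ndarray, mask: np.ndarray, alpha: float = 0.45) -> np.ndarray:
    """RGB overlay: cavity in red, myocardium in green, other classes blue."""
    rgb = np.stack([image] * 3, axis=-1).astype(np.float64)
    colors = {1: (255, 0, 0), 2: (0, 255, 0)}
    for c in np.unique(mask):
        if c == 0:
            continue
        color = colors.get(int(c), (0, 128, 255))
        sel = mask == c
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * np.asarray(color)
    return np.clip(rgb + 0.5, 0, 255).astype(np.uint8)


def _stage_predict(config: RunConfig, out: Path) -> list[str]:
    from PIL import Image

    ckpt = out / "checkpoint.npz"
    if not ckpt.exists():
        raise FileNotFoundError("checkpoint.npz missing; run the train stage first")
    if not config.predict_image:
        raise ValueError("predict stage needs predict_image pointing at a PNG")
    net = load_network(ckpt)
    image = np.asarray(Image.open(config.predict_image).convert("L"))
    mask = predict_mask(net, image)
    pred_dir = out / "predictions"
    pred_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(config.predict_image).stem
    mask_path = pred_dir / f"{stem}_mask.png"
    Image.fromarray(mask, mode="L").save(mask_path)
    over_path = pred_dir / f"{stem}_overlay.png"
    Image.fromarray(overlay_mask(image, mask), mode="RGB").save(over_path)
    return [str(mask_path), str(over_path)]


_STAGE_FNS = {
    "phantom": _stage_phantom,
    "convert": _stage_convert,
    "weights": _stage_weights,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "predict": _stage_predict,
}


def run_pipeline(config: RunConfig, stages: list[str]) -> dict[str, list[str]]:
    """Run the requested stages in canonical order; returns stage -> outputs."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    results = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        outputs = _STAGE_FNS[stage](config, out)
        _log_stage(out, stage, config, outputs)
        results[stage] = outputs
    return results
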