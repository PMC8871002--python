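"""The 15-layer encoder-decoder FCN: spec, shape accounting, instantiation.

Layer order: image input; conv(16)+BN+ReLU; 2x2/2 max pool;
conv(32)+BN+ReLU; conv(64)+BN+ReLU; 4x4/2 transpose conv(16);
conv(num_classes); softmax; pixel classification.  All convolutions are
3x3 same-padded; the transpose convolution upsamples back to the input
grid, so the class map has the input's spatial size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .layers import (
    BatchNorm2D,
    Conv2D,
    Identity,
    Layer,
    MaxPool2x2,
    ReLU,
    Softmax,
    TransposeConv2D,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "Network",
    "default_network_spec",
    "build_network",
    "forward_shapes",
    "count_learnables",
    "predict_mask",
    "save_network",
    "load_network",
]

LAYER_KINDS = {
    "input",
    "convolution",
    "batch_norm",
    "relu",
    "max_pool",
    "transpose_convolution",
    "softmax",
    "pixel_classification",
}


@dataclass(frozen=True)
class LayerSpec:
    index: int
    kind: str
    kernel: tuple[int, int] | None = None
    filters: int | None = None
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (256, 192, 1)  # H, W, C
    num_classes: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))

    def to_yaml(self) -> str:
        doc = {
            "input_shape": list(self.input_shape),
            "num_classes": self.num_classes,
            "layers": [
                {
                    "index": l.index,
                    "kind": l.kind,
                    "kernel": list(l.kernel) if l.kernel else None,
                    "filters": l.filters,
                    "stride": l.stride,
                    "padding": l.padding,
                }
                for l in self.layers
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        layers = tuple(
            LayerSpec(
                index=d["index"],
                kind=d["kind"],
                kernel=tuple(d["kernel"]) if d.get("kernel") else None,
                filters=d.get("filters"),
                stride=d.get("stride", 1),
                padding=d.get("padding", "same"),
            )
            for d in doc["layers"]
        )
        return cls(
            layers=layers,
            input_shape=tuple(doc["input_shape"]),
            num_classes=doc["num_classes"],
        )

    def spec_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def default_network_spec(
    num_classes: int = 3,
    input_shape: tuple[int, int, int] = (256, 192, 1),
    filters: tuple[int, int, int, int] = (16, 32, 64, 16),
) -> NetworkSpec:
    """The canonical 15-layer list (encoder 16/32/64, decoder 16, C classes)."""
    f1, f2, f3, f4 = filters
    ls = [
        LayerSpec(1, "input"),
        LayerSpec(2, "convolution", kernel=(3, 3), filters=f1),
        LayerSpec(3, "batch_norm"),
        LayerSpec(4, "relu"),
        LayerSpec(5, "max_pool", kernel=(2, 2), stride=2),
        LayerSpec(6, "convolution", kernel=(3, 3), filters=f2),
        LayerSpec(7, "batch_norm"),
        LayerSpec(8, "relu"),
        LayerSpec(9, "convolution", kernel=(3, 3), filters=f3),
        LayerSpec(10, "batch_norm"),
        LayerSpec(11, "relu"),
        LayerSpec(12, "transpose_convolution", kernel=(4, 4), filters=f4, stride=2),
        LayerSpec(13, "convolution", kernel=(3, 3), filters=num_classes),
        LayerSpec(14, "softmax"),
        LayerSpec(15, "pixel_classification"),
    ]
    return NetworkSpec(layers=tuple(ls), input_shape=input_shape, num_classes=num_classes)


class SpecError(ValueError):
    """Raised when a layer list cannot be instantiated consistently."""


def _check_layer(l: LayerSpec) -> None:
    if l.kind == "convolution":
        if l.kernel != (3, 3):
            raise SpecError(f"layer {l.index}: convolutions must use 3x3 kernels, got {l.kernel}")
        if l.padding != "same":
            raise SpecError(f"layer {l.index}: convolutions must be same-padded")
        if not l.filters or l.filters < 1:
            raise SpecError(f"layer {l.index}: convolution needs a positive filter count")
    elif l.kind == "max_pool":
        if l.kernel != (2, 2) or l.stride != 2:
            raise SpecError(f"layer {l.index}: pooling must be 2x2 stride 2, got {l.kernel}/{l.stride}")
    elif l.kind == "transpose_convolution":
        if l.kernel != (4, 4) or l.stride != 2:
            raise SpecError(
                f"layer {l.index}: transpose convolution must be 4x4 stride 2, got {l.kernel}/{l.stride}"
            )
        if not l.filters or l.filters < 1:
            raise SpecError(f"layer {l.index}: transpose convolution needs a positive filter count")


def forward_shapes(spec: NetworkSpec) -> list[tuple[int, int, int]]:
    """Activation shape (H, W, C) after each layer, computed symbolically."""
    shapes: list[tuple[int, int, int]] = []
    h, w, c = spec.input_shape
    for l in spec.layers:
        _check_layer(l)
        if l.kind == "input":
            pass
        elif l.kind == "convolution":
            c = l.filters
        elif l.kind in ("batch_norm", "relu", "softmax", "pixel_classification"):
            pass
        elif l.kind == "max_pool":
            if h % 2 or w % 2:
                raise SpecError(
                    f"layer {l.index}: spatial dims {h}x{w} not divisible by pooling stride 2"
                )
            h, w = h // 2, w // 2
        elif l.kind == "transpose_convolution":
            h, w = 2 * h, 2 * w
            c = l.filters
        shapes.append((h, w, c))
    return shapes


def count_learnables(spec: NetworkSpec) -> int:
    """Total elements of every weight/bias/offset/scale tensor in the spec."""
    total = 0
    c = spec.input_shape[2]
    for l in spec.layers:
        _check_layer(l)
        if l.kind == "convolution":
            kh, kw = l.kernel
            total += kh * kw * c * l.filters + l.filters
            c = l.filters
        elif l.kind == "batch_norm":
            total += 2 * c
        elif l.kind == "transpose_convolution":
            kh, kw = l.kernel
            total += kh * kw * l.filters * c + l.filters
            c = l.filters
    return total


class Network:
    """An instantiated FCN: an ordered list of live layers plus its spec."""

    def __init__(self, spec: NetworkSpec, layers: list[Layer], seed: int):
        self.spec = spec
        self.layers = layers
        self.seed = seed
        # position of the softmax layer; training backpropagates from the
        # logits feeding it, with the softmax folded into the loss gradient
        self._softmax_pos = next(
            (i for i, l in enumerate(spec.layers) if l.kind == "softmax"), len(layers)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Full pass: per-pixel class probabilities, shape (N, C, H, W)."""
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers[: self._softmax_pos]:
            x = layer.forward(x, train=train)
        return x

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers[: self._softmax_pos]):
            d = layer.backward(d)
        return d

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples in layer order."""
        out = []
        for i, layer in enumerate(self.layers):
            p, g = layer.params, layer.grads
            for name in p:
                out.append((f"L{i + 1}_{name}", p[name], g[name]))
        return out

    def set_parameter(self, name: str, value: np.ndarray) -> None:
        idx, _, pname = name.partition("_")
        layer = self.layers[int(idx[1:]) - 1]
        layer.params[pname][...] = value

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: val for name, val, _ in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2D):
                state[f"L{i + 1}_running_mean"] = layer.running_mean
                state[f"L{i + 1}_running_var"] = layer.running_var
        return state


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate the spec with He-uniform init from a seeded generator."""
    forward_shapes(spec)  # raises SpecError on the first inconsistency
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    c = spec.input_shape[2]
    for l in spec.layers:
        if l.kind == "input":
            layers.append(Identity())
        elif l.kind == "convolution":
            layers.append(Conv2D(c, l.filters, kernel=l.kernel[0], rng=rng))
            c = l.filters
        elif l.kind == "batch_norm":
            layers.append(BatchNorm2D(c))
        elif l.kind == "relu":
            layers.append(ReLU())
        elif l.kind == "max_pool":
            layers.append(MaxPool2x2())
        elif l.kind == "transpose_convolution":
            layers.append(TransposeConv2D(c, l.filters, kernel=l.kernel[0], stride=l.stride, rng=rng))
            c = l.filters
        elif l.kind == "softmax":
            layers.append(Softmax())
        elif l.kind == "pixel_classification":
            layers.append(Identity())
    return Network(spec, layers, seed)


def image_to_input(image: np.ndarray) -> np.ndarray:
    """8-bit image -> (1, 1, H, W) float32 in [0, 1]."""
    return (np.asarray(image, dtype=np.float32) / 255.0)[None, None]


def predict_mask(network: Network, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class map; ties break toward the lowest class index."""
    image = np.asarray(image)
    h, w, _ = network.spec.input_shape
    if image.shape != (h, w):
        raise ValueError(f"image shape {image.shape} does not match network input {(h, w)}")
    probs = network.forward(image_to_input(image), train=False)
    return probs[0].argmax(axis=0).astype(np.uint8)


def save_network(network: Network, path: str | Path) -> None:
    """Checkpoint: npz of parameters/running stats + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **network.state_arrays())
    sidecar = {
        "spec_yaml": network.spec.to_yaml(),
        "spec_hash": network.spec.spec_hash(),
        "seed": network.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: str | Path) -> Network:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec.from_yaml(sidecar["spec_yaml"])
    net = build_network(spec, seed=sidecar["seed"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for name in data.files:
            if name.endswith("running_mean") or name.endswith("running_var"):
                idx = int(name.split("_")[0][1:]) - 1
                layer = net.layers[idx]
                if name.endswith("running_mean"):
                    layer.running_mean = data[name]
                else:
                    layer.running_var = data[name]
            else:
                net.set_parameter(name, data[name])
    return net
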