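"""Class-weighted cross-entropy training with SGDM/Adam/RMSProp.

The loss is normalized by the sum of the per-pixel weights actually
applied, so rescaling all class weights by a constant leaves it unchanged
and the magnitude is comparable across imbalance levels.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .nn.network import Network, NetworkSpec, build_network, image_to_input
from .nn.solvers import SOLVERS, make_solver
from .phantom import LabeledSlice
from .weighting import ClassWeights, compute_class_weights

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "weighted_cross_entropy",
    "wce_loss_and_grad",
    "minibatch_accuracy",
    "train",
    "hyperparameter_sweep",
]

EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    solver: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 150
    mini_batch: int = 4
    seed: int = 0
    momentum: float = 0.9  # sgdm only
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"solver must be one of {sorted(SOLVERS)}, got {self.solver!r}")
        # learning_rate 0 is allowed as a degenerate diagnostic (null update)
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mini_batch < 1:
            raise ValueError("mini_batch must be >= 1")

    def make_solver(self):
        if self.solver == "sgdm":
            return make_solver("sgdm", self.learning_rate, momentum=self.momentum)
        return make_solver(self.solver, self.learning_rate)


@dataclass
class TrainHistory:
    """Per-iteration loss/accuracy trace plus per-epoch aggregates."""

    records: list[dict] = field(default_factory=list)
    iterations_per_epoch: int = 0
    wall_time: float = 0.0

    def append(self, epoch: int, iteration: int, loss: float, accuracy: float) -> None:
        self.records.append(
            {"epoch": epoch, "iteration": iteration, "loss": loss, "accuracy": accuracy}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def epoch_means(self) -> pd.DataFrame:
        return self.to_frame().groupby("epoch")[["loss", "accuracy"]].mean()

    @property
    def final_accuracy(self) -> float:
        return self.records[-1]["accuracy"] if self.records else float("nan")

    @property
    def final_loss(self) -> float:
        return self.records[-1]["loss"] if self.records else float("nan")


def _weight_vector(weights: ClassWeights | np.ndarray | Sequence[float] | None,
                   num_classes: int) -> np.ndarray:
    if weights is None:
        return np.ones(num_classes, dtype=np.float64)
    if isinstance(weights, ClassWeights):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=np.float64)
    if w.shape != (num_classes,):
        raise ValueError(f"expected {num_classes} class weights, got shape {w.shape}")
    return w


def weighted_cross_entropy(
    probabilities: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
) -> float:
    """Weight-normalized pixel cross-entropy.

    ``L = -(sum_p w[t(p)] * log prob_p[t(p)]) / sum_p w[t(p)]`` with the
    true-class probability clipped at 1e-12.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    target = np.asarray(target)
    if probs.ndim == 3:  # (C, H, W) single item
        probs = probs[None]
        target = target[None]
    n, c, h, w = probs.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} incompatible with probabilities {probs.shape}")
    wvec = _weight_vector(weights, c)
    p_true = np.take_along_axis(probs, target[:, None], axis=1)[:, 0]
    wpix = wvec[target]
    wsum = wpix.sum()
    if wsum == 0:
        return 0.0
    return float(-(wpix * np.log(np.clip(p_true, EPS, None))).sum() / wsum)


def wce_loss_and_grad(
    logits: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss, probabilities, and the analytic gradient w.r.t. the logits.

    Softmax folded in: ``dL/dz = w[t] * (p - onehot(t)) / sum(w[t])``.
    """
    z = np.asarray(logits, dtype=np.float64)
    n, c, h, w = z.shape
    e = np.exp(z - z.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    loss = weighted_cross_entropy(probs, target, weights)
    wvec = _weight_vector(weights, c)
    wpix = wvec[np.asarray(target)]
    wsum = wpix.sum()
    if wsum == 0:
        return loss, probs, np.zeros_like(z, dtype=np.float32)
    grad = probs.copy()
    idx = np.asarray(target)[:, None]
    np.put_along_axis(grad, idx, np.take_along_axis(grad, idx, axis=1) - 1.0, axis=1)
    grad *= wpix[:, None] / wsum
    return loss, probs, grad.astype(np.float32)


def minibatch_accuracy(probabilities: np.ndarray, target: np.ndarray) -> float:
    """Percentage of pixels whose argmax class equals the target."""
    probs = np.asarray(probabilities)
    target = np.asarray(target)
    if probs.ndim == 3:
        probs = probs[None]
        target = target[None]
    pred = probs.argmax(axis=1)
    if pred.shape != target.shape:
        raise ValueError(f"target shape {target.shape} incompatible with probabilities")
    return float(100.0 * (pred == target).mean())


def _stack_batch(slices: Sequence[LabeledSlice]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([image_to_input(s.image)[0] for s in slices])
    t = np.stack([np.asarray(s.mask, dtype=np.int64) for s in slices])
    return x, t


def train(
    network: Network,
    dataset: Sequence[LabeledSlice],
    config: TrainConfig,
    weights: ClassWeights | np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[Network, TrainHistory]:
    """Mini-batch training; deterministic given (dataset, config, seed).

    ``weights`` defaults to inverse-frequency weights computed from the
    given dataset's masks.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    num_classes = network.spec.num_classes
    if weights is None:
        weights = compute_class_weights((s.mask for s in dataset), num_classes)

    solver = config.make_solver()
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    iters = math.ceil(n / config.mini_batch)
    history = TrainHistory(iterations_per_epoch=iters)
    t0 = time.perf_counter()

    step = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        for it in range(iters):
            batch = [dataset[i] for i in order[it * config.mini_batch : (it + 1) * config.mini_batch]]
            x, t = _stack_batch(batch)
            logits = network.forward_logits(x, train=True)
            loss, probs, dlogits = wce_loss_and_grad(logits, t, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch} iteration {it + 1}; "
                    f"solver={config.solver} lr={config.learning_rate}"
                )
            acc = minibatch_accuracy(probs, t)
            network.backward_from_logits(dlogits)
            solver.step(network.parameters())
            step += 1
            history.append(epoch, step, loss, acc)
            if verbose:
                print(f"epoch {epoch:3d} iter {step:5d} loss {loss:.4f} acc {acc:6.2f}%")
    history.wall_time = time.perf_counter() - t0
    return network, history


def hyperparameter_sweep(
    grid: dict[str, Iterable],
    train_slices: Sequence[LabeledSlice],
    val_slices: Sequence[LabeledSlice] = (),
    spec: NetworkSpec | None = None,
    base_config: TrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one network per grid combination; one result row each.

    ``grid`` maps TrainConfig field names (solver, learning_rate, epochs,
    mini_batch) to iterables of values.  Rows carry the final mini-batch
    accuracy/loss and, when validation slices are given, held-out pixel
    accuracy and mean foreground dice.
    """
    from .metrics import MetricAccumulator  # local import to avoid a cycle
    from .nn.network import default_network_spec, predict_mask

    if not grid:
        raise ValueError("empty hyper-parameter grid")
    if spec is None:
        spec = default_network_spec()
    base = base_config or TrainConfig(seed=seed)

    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(list(grid[k]) for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)), seed=seed)
        net = build_network(spec, seed=seed)
        net, hist = train(net, train_slices, cfg)
        row = {k: getattr(cfg, k) for k in ("solver", "learning_rate", "epochs", "mini_batch")}
        row["final_accuracy"] = hist.final_accuracy
        row["final_loss"] = hist.final_loss
        if val_slices:
            acc = MetricAccumulator(spec.num_classes)
            for s in val_slices:
                acc.add(predict_mask(net, s.image), np.asarray(s.mask))
            report = acc.report()
            row["val_global_accuracy"] = report.global_accuracy
            row["val_mean_dice"] = report.mean_dice
        rows.append(row)
    return pd.DataFrame(rows)
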