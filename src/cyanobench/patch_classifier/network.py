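"""The patch-classification network: configuration, construction, training.

Architecture (fixed shape, configurable widths): four blocks of
[3×3 conv → batch norm → leaky ReLU → 2×2/2 max pool], so the 32×32 input
halves to 2×2 over the four blocks, followed by a single fully connected
layer producing class logits. Training minimizes cross-entropy with Adam
(learning rate 1e-4) for a fixed number of epochs (default 60) with no
early stopping. Inputs are per-patch, per-channel standardized so the
network sees intensity contrasts, not absolute camera offsets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Flatten,
    LeakyReLU,
    Linear,
    MaxPool2x2,
    Sequential,
    cross_entropy,
    softmax,
)

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "build_network",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

PATCH_SIZE = 32  # fixed input size; ~1.5-2x a cell so some context is included
N_BLOCKS = 4


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the patch classifier.

    ``patch_size`` is fixed at 32 and ``conv_filters`` must list exactly
    four widths (one per block). ``n_channels`` is capped at 6, the
    framework's channel limit.
    """

    n_channels: int = 2
    n_classes: int = 4
    patch_size: int = PATCH_SIZE
    conv_filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    learning_rate: float = 1e-4
    max_epochs: int = 60
    batch_size: int = 64
    seed: int = 0
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.patch_size != PATCH_SIZE:
            raise ValueError(f"patch_size is fixed at {PATCH_SIZE}")
        if self.patch_size % 2**N_BLOCKS != 0:
            raise ValueError("patch_size must be divisible by 16 (four 2x poolings)")
        if not 1 <= self.n_channels <= 6:
            raise ValueError("n_channels must be 1-6")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.conv_filters) != N_BLOCKS:
            raise ValueError(f"conv_filters must have exactly {N_BLOCKS} entries")


class TrainedClassifier:
    """A (possibly untrained) network plus its config, classes and history."""

    def __init__(
        self,
        config: ClassifierConfig,
        net: Sequential,
        class_names: tuple[str, ...],
    ):
        self.config = config
        self.net = net
        self.class_names = class_names
        self.training_history: list[dict] = []

    # -- inference ---------------------------------------------------------

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        """(N, 32, 32, C) or (32, 32, C) -> standardized NCHW float32."""
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:3] != (self.config.patch_size,) * 2:
            raise ValueError(
                f"patches must be (N, {self.config.patch_size}, "
                f"{self.config.patch_size}, C), got {x.shape}"
            )
        if x.shape[3] != self.config.n_channels:
            raise ValueError(
                f"expected {self.config.n_channels} channels, got {x.shape[3]}"
            )
        x = x.transpose(0, 3, 1, 2)  # NHWC -> NCHW
        mean = x.mean(axis=(2, 3), keepdims=True)
        sd = x.std(axis=(2, 3), keepdims=True)
        return (x - mean) / (sd + 1e-6)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (N, n_classes); rows sum to 1."""
        x = self._prepare(patches)
        probs = []
        for i in range(0, x.shape[0], 256):
            logits = self.net.forward(x[i : i + 256], train=False)
            probs.append(softmax(logits.astype(np.float64)))
        return np.concatenate(probs) if probs else np.empty((0, self.config.n_classes))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Predicted class indices; argmax ties break to the lowest index."""
        return self.predict_proba(patches).argmax(axis=1)

    def history_hash(self) -> str:
        """Stable hash of the training history, for reproducibility checks."""
        import hashlib

        payload = json.dumps(self.training_history, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def build_network(
    cfg: ClassifierConfig, class_names: tuple[str, ...] | None = None
) -> TrainedClassifier:
    """Construct an initialized (untrained) classifier.

    Initialization is He-normal, drawn from a generator seeded by
    ``cfg.seed``, so two constructions with the same config are identical.
    """
    rng = np.random.default_rng(cfg.seed)
    layers = []
    in_ch = cfg.n_channels
    for f in cfg.conv_filters:
        layers += [
            Conv2d(in_ch, f, rng),
            BatchNorm2d(f),
            LeakyReLU(cfg.leaky_slope),
            MaxPool2x2(),
        ]
        in_ch = f
    final_spatial = cfg.patch_size // 2**N_BLOCKS
    layers += [Flatten(), Linear(in_ch * final_spatial**2, cfg.n_classes, rng)]
    names = class_names or tuple(f"class_{i}" for i in range(cfg.n_classes))
    if len(names) != cfg.n_classes:
        raise ValueError("class_names length must equal n_classes")
    return TrainedClassifier(cfg, Sequential(layers), tuple(names))


def train(
    model: TrainedClassifier,
    patches: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Train in place for exactly ``max_epochs`` epochs; returns the model.

    ``patches`` is (N, 32, 32, C) in channel-last order, ``labels`` integer
    class indices. Batches are reshuffled every epoch from a generator
    seeded by the config seed, so training is bit-reproducible on a fixed
    platform. Zero epochs returns the model unchanged.
    """
    cfg = cfg or model.config
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1 or labels.size != np.asarray(patches).shape[0]:
        raise ValueError("labels must be 1D with one entry per patch")
    if labels.size and (labels.min() < 0 or labels.max() >= cfg.n_classes):
        raise ValueError("labels out of range for n_classes")
    present = np.unique(labels)
    if present.size < cfg.n_classes:
        missing = sorted(set(range(cfg.n_classes)) - set(present.tolist()))
        warnings.warn(f"classes absent from training set: {missing}", stacklevel=2)
    if cfg.max_epochs == 0:
        return model

    x = model._prepare(patches)
    opt = Adam(model.net.named_params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], labels[idx]
            logits = model.net.forward(xb, train=True)
            loss, dlogits = cross_entropy(logits, yb)
            model.net.backward(dlogits)
            opt.step(model.net.named_grads())
            losses.append(loss * idx.size)
            correct += int((logits.argmax(axis=1) == yb).sum())
        model.training_history.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
        )
    return model


def save_checkpoint(model: TrainedClassifier, path: str | Path) -> None:
    """Serialize config, class names, parameters and buffers to one file."""
    meta = {
        "format_version": 1,
        "config": asdict(model.config),
        "class_names": list(model.class_names),
        "training_history": model.training_history,
    }
    arrays = {f"param/{k}": v for k, v in model.net.named_params().items()}
    arrays |= {f"state/{k}": v for k, v in model.net.named_state().items()}
    with open(Path(path), "wb") as fh:  # plain open keeps the exact filename
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
            **arrays,
        )


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    """Rebuild a classifier from :func:`save_checkpoint` output."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
        cfg = ClassifierConfig(**cfg_d)
        model = build_network(cfg, tuple(meta["class_names"]))
        model.training_history = meta["training_history"]
        params = model.net.named_params()
        state = model.net.named_state()
        for k, v in params.items():
            v[...] = data[f"param/{k}"]
        for k, v in state.items():
            v[...] = data[f"state/{k}"]
    return model
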