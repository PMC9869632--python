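"""Six-class probabilistic patch classifier: contract, augmentations, trainer.

The classifier contract is minimal: a ``predict`` that maps one RGB patch to
a six-way probability vector, plus file serialization. The reference
implementation is a compact CNN (see :mod:`uroslide.nn`) operating on a
mean-pooled view of the patch; any stronger network honouring the contract
can be dropped in.

Training follows a fixed recipe: cross-entropy loss, stochastic gradient
descent with momentum 0.9 and weight decay 1e-4, initial learning rate 0.01
multiplied by 0.1 at epochs 18 and 24, 30 epochs total. Batches are
class-balanced (HGMI examples are scarce because they come from junction
points only), and five augmentation families — translation, rotation,
scaling, flipping, colour jitter — are applied on the fly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np

from .labels import ALL_CLASSES, N_CLASSES, LabelClass
from .nn import SGDMomentum, SmallCNN
from .sampling import LabeledPatch, extract_patch

__all__ = [
    "TrainConfig",
    "PatchPrediction",
    "PatchClassifier",
    "CNNPatchClassifier",
    "ConstantClassifier",
    "PatchDataset",
    "learning_rate",
    "augment",
    "train",
    "save_classifier",
    "load_classifier",
    "write_training_log",
]

AUGMENTATION_FAMILIES = ("translation", "rotation", "scaling", "flipping",
                         "colour_jitter")


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.01
    lr_factor: float = 0.1
    milestones: tuple[int, ...] = (18, 24)   # 1-based epochs; drop applies AT the epoch
    epochs: int = 30
    momentum: float = 0.9
    weight_decay: float = 0.0001
    batch_size: int = 64
    seed: int = 0
    augmentations: tuple[str, ...] = AUGMENTATION_FAMILIES

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.lr_factor <= 0:
            raise ValueError("rates must be positive")
        if any(not (1 <= m <= self.epochs) for m in self.milestones):
            raise ValueError("milestones must lie within [1, epochs]")
        bad = set(self.augmentations) - set(AUGMENTATION_FAMILIES)
        if bad:
            raise ValueError(f"unknown augmentation families: {sorted(bad)}")


@dataclass(frozen=True)
class PatchPrediction:
    """Probability over the six classes, in channel order."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (N_CLASSES,):
            raise ValueError(f"expected a {N_CLASSES}-vector")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be in [0,1] and sum to 1")

    @property
    def predicted_class(self) -> LabelClass:
        return ALL_CLASSES[int(np.argmax(self.probabilities))]


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """LR at a 1-based epoch: initial * factor^(#milestones <= epoch)."""
    if not (1 <= epoch <= cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [1, {cfg.epochs}]")
    drops = sum(1 for m in cfg.milestones if m <= epoch)
    return cfg.initial_lr * cfg.lr_factor ** drops


# ---------------------------------------------------------------------------
# augmentation

def _nearest_resize(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    h, w = img.shape[:2]
    yi = np.clip((np.arange(out_hw[0]) + 0.5) * h / out_hw[0], 0, h - 1).astype(int)
    xi = np.clip((np.arange(out_hw[1]) + 0.5) * w / out_hw[1], 0, w - 1).astype(int)
    return img[np.ix_(yi, xi)]


def augment(patch: np.ndarray, rng: np.random.Generator,
            cfg: TrainConfig) -> np.ndarray:
    """Apply one independently sampled transform per enabled family.

    Input is a square HxWxC raster (uint8 or float, 0-255 scale); output has
    the same shape and dtype. With all families disabled this is the
    identity. Deterministic for a fixed generator state.
    """
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    out = patch.astype(np.float32)
    size = out.shape[0]
    fams = cfg.augmentations
    if "translation" in fams:
        lim = max(1, size // 8)
        dy, dx = rng.integers(-lim, lim + 1, size=2)
        out = np.roll(out, (int(dy), int(dx)), axis=(0, 1))
    if "rotation" in fams:
        out = np.rot90(out, k=int(rng.integers(0, 4)), axes=(0, 1))
    if "scaling" in fams:
        s = float(rng.uniform(1.0, 1.2))
        crop = max(4, int(round(size / s)))
        off = (size - crop) // 2
        out = _nearest_resize(out[off:off + crop, off:off + crop], (size, size))
    if "flipping" in fams:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if "colour_jitter" in fams:
        scale = rng.uniform(0.9, 1.1, size=out.shape[-1]).astype(np.float32)
        shift = rng.uniform(-8, 8, size=out.shape[-1]).astype(np.float32)
        out = np.clip(out * scale + shift, 0, 255)
    out = np.ascontiguousarray(out)
    if patch.dtype == np.uint8:
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out.astype(patch.dtype)


# ---------------------------------------------------------------------------
# classifier contract and reference CNN implementation

class PatchClassifier(Protocol):
    patch_size: int

    def predict(self, patch: np.ndarray) -> PatchPrediction: ...

    def predict_batch(self, patches: np.ndarray) -> np.ndarray: ...


def pool_patch(patch: np.ndarray, input_size: int) -> np.ndarray:
    """Mean-pool a (S,S,3) patch to (input_size, input_size, 3) float32.

    S must be a multiple of input_size; pooling blocks align with the
    stride-32 heatmap grid, which lets dense inference pool whole ROIs once.
    """
    s = patch.shape[0]
    if s % input_size != 0:
        raise ValueError(f"patch size {s} not divisible by {input_size}")
    f = s // input_size
    return patch.astype(np.float32).reshape(
        input_size, f, input_size, f, 3).mean(axis=(1, 3))


class CNNPatchClassifier:
    """Reference classifier: mean-pooled patch into a compact CNN."""

    def __init__(self, patch_size: int = 256, input_size: int = 32,
                 seed: int = 0, net: SmallCNN | None = None):
        if patch_size % input_size != 0:
            raise ValueError("patch_size must be a multiple of input_size")
        self.patch_size = patch_size
        self.input_size = input_size
        self.net = net if net is not None else SmallCNN(input_size=input_size,
                                                        seed=seed)

    def _to_net_input(self, pooled_hwc: np.ndarray) -> np.ndarray:
        x = pooled_hwc.astype(np.float32) / 255.0 - 0.5
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def predict(self, patch: np.ndarray) -> PatchPrediction:
        patch = np.asarray(patch)
        if patch.shape != (self.patch_size, self.patch_size, 3):
            raise ValueError(
                f"expected patch of shape {(self.patch_size, self.patch_size, 3)}, "
                f"got {patch.shape}")
        pooled = pool_patch(patch, self.input_size)[None]
        return PatchPrediction(self.predict_batch_pooled(pooled)[0])

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        """(N,S,S,3) uint8 -> (N,6) float64 probabilities."""
        pooled = np.stack([pool_patch(p, self.input_size) for p in patches])
        return self.predict_batch_pooled(pooled)

    def predict_batch_pooled(self, pooled_hwc: np.ndarray) -> np.ndarray:
        """(N,input,input,3) 0-255 floats -> (N,6) probabilities."""
        return self.net.predict_proba(self._to_net_input(pooled_hwc)).astype(np.float64)


class ConstantClassifier:
    """Outputs one fixed probability vector everywhere (testing stub)."""

    def __init__(self, probabilities: Sequence[float], patch_size: int = 256):
        self.patch_size = patch_size
        self._p = np.asarray(probabilities, dtype=np.float64)

    def predict(self, patch: np.ndarray) -> PatchPrediction:
        return PatchPrediction(self._p.copy())

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        return np.tile(self._p, (len(patches), 1))

    def predict_batch_pooled(self, pooled: np.ndarray) -> np.ndarray:
        return np.tile(self._p, (len(pooled), 1))


def save_classifier(model: CNNPatchClassifier, path: str | Path) -> None:
    """Single self-describing weights file (npz with embedded config)."""
    config = {
        "patch_size": model.patch_size,
        "input_size": model.input_size,
        "channels": list(model.net.channels),
        "hidden": model.net.hidden,
        "n_classes": model.net.n_classes,
    }
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8), **model.net.params)


def load_classifier(path: str | Path) -> CNNPatchClassifier:
    data = np.load(path)
    config = json.loads(bytes(data["__config__"]).decode())
    net = SmallCNN(input_size=config["input_size"],
                   channels=tuple(config["channels"]), hidden=config["hidden"],
                   n_classes=config["n_classes"])
    for k in net.params:
        net.params[k] = data[k].copy()
    return CNNPatchClassifier(patch_size=config["patch_size"],
                              input_size=config["input_size"], net=net)


# ---------------------------------------------------------------------------
# training

@dataclass
class PatchDataset:
    """Pooled patch pixels (N, input, input, 3 float32, 0-255) and labels."""

    pooled: np.ndarray
    labels: np.ndarray
    input_size: int = 32

    @classmethod
    def from_patches(cls, patches: Sequence[LabeledPatch],
                     images: Mapping[str, np.ndarray] | None = None,
                     image_provider=None, input_size: int = 32) -> "PatchDataset":
        """Build from patch records plus image access (mapping or callable)."""
        if image_provider is None:
            if images is None:
                raise ValueError("provide images or image_provider")
            image_provider = images.__getitem__
        pooled = np.empty((len(patches), input_size, input_size, 3), np.float32)
        labels = np.empty(len(patches), np.int64)
        cache_id, cache_img = None, None
        for i, p in enumerate(patches):
            if p.slide_id != cache_id:
                cache_id, cache_img = p.slide_id, image_provider(p.slide_id)
            pooled[i] = pool_patch(extract_patch(cache_img, p), input_size)
            labels[i] = p.label.channel_index
        return cls(pooled=pooled, labels=labels, input_size=input_size)

    def extend(self, other: "PatchDataset") -> "PatchDataset":
        return PatchDataset(np.concatenate([self.pooled, other.pooled]),
                            np.concatenate([self.labels, other.labels]),
                            self.input_size)

    def __len__(self) -> int:
        return len(self.labels)


def train(train_ds: PatchDataset, cfg: TrainConfig,
          tune_ds: PatchDataset | None = None,
          patch_size: int = 256) -> tuple[CNNPatchClassifier, list[dict]]:
    """Train the reference CNN; returns the final-epoch model and a log.

    The log has one record per epoch: epoch, lr, train_loss, train_acc and
    (when a tuning split is given) tune_acc — the learning curves. Batches
    draw classes uniformly so scarce classes are not swamped. Fully seeded.
    """
    present = set(int(c) for c in np.unique(train_ds.labels))
    missing = [c.name for c in ALL_CLASSES if c.channel_index not in present]
    if missing:
        raise ValueError(f"training data missing classes: {missing}")
    rng = np.random.default_rng(cfg.seed)
    model = CNNPatchClassifier(patch_size=patch_size,
                               input_size=train_ds.input_size,
                               seed=int(rng.integers(0, 2**31 - 1)))
    opt = SGDMomentum(model.net.params, cfg.momentum, cfg.weight_decay)
    by_class = [np.flatnonzero(train_ds.labels == c) for c in range(N_CLASSES)]
    n_batches = max(1, -(-len(train_ds) // cfg.batch_size))
    log: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate(epoch, cfg)
        losses, correct, seen = [], 0, 0
        for _ in range(n_batches):
            cls_draw = rng.integers(0, N_CLASSES, size=cfg.batch_size)
            idx = np.array([by_class[c][rng.integers(0, len(by_class[c]))]
                            for c in cls_draw])
            batch = np.stack([augment(train_ds.pooled[i], rng, cfg) for i in idx])
            y = train_ds.labels[idx]
            x = model._to_net_input(batch)
            loss, logits, grads = model.net.loss_and_grads(x, y)
            opt.step(model.net.params, grads, lr)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y).sum())
            seen += len(y)
        rec = {"epoch": epoch, "lr": lr,
               "train_loss": float(np.mean(losses)),
               "train_acc": correct / seen}
        if tune_ds is not None and len(tune_ds) > 0:
            probs = model.predict_batch_pooled(tune_ds.pooled)
            rec["tune_acc"] = float(np.mean(probs.argmax(axis=1) == tune_ds.labels))
        log.append(rec)
    return model, log


def write_training_log(log: list[dict], path: str | Path) -> None:
    cols = ["epoch", "lr", "train_loss", "train_acc", "tune_acc"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for rec in log:
            fh.write(",".join(str(rec.get(c, "")) for c in cols) + "\n")
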