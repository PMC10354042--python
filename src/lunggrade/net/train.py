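"""Training loop for the grader network.

Pixelwise cross-entropy on the train split (Background pixels carry no
loss: the library is pre-balanced by area and Background is produced only
by tissue masking at inference), Adam with a fixed learning rate,
per-epoch validation pixel accuracy, best-validation weights returned.
Fully seeded and deterministic on a fixed device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..patches import Patch, PatchLibrary
from ..types import ClassLabel
from .layers import Adam, cross_entropy_loss, softmax_channels
from .model import GraderNetwork

log = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    epochs: int = 20
    minibatch: int = 128
    initial_lr: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.minibatch < 1 or self.initial_lr <= 0:
            raise ValueError("invalid training configuration")


def _to_arrays(patches: list[Patch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.rgb for p in patches]).astype(np.float32) / 255.0 - 0.5
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([p.labels for p in patches]).astype(np.int64)
    return x, y


def _targets(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (label - 1) and the Background ignore mask."""
    ignore = labels == int(ClassLabel.BACKGROUND)
    t = np.maximum(labels - 1, 0)
    return t, ignore


def pixel_accuracy(net: GraderNetwork, x: np.ndarray, labels: np.ndarray, batch: int = 8) -> float:
    """Fraction of non-Background pixels argmax-classified correctly."""
    t, ignore = _targets(labels)
    correct = total = 0
    for i in range(0, len(x), batch):
        logits = net.forward_logits(x[i : i + batch])
        pred = logits.argmax(axis=1)
        valid = ~ignore[i : i + batch]
        correct += int((pred[valid] == t[i : i + batch][valid]).sum())
        total += int(valid.sum())
    return correct / max(total, 1)


def train(
    net: GraderNetwork, library: PatchLibrary, cfg: TrainingConfig
) -> tuple[GraderNetwork, list[dict]]:
    """Train on the library's train split, validating each epoch.

    Returns the network carrying the best-validation weights and a
    per-epoch log of loss and pixel accuracy.
    """
    train_patches = library.subset("train")
    val_patches = library.subset("validation")
    if not train_patches or not val_patches:
        raise ValueError("library needs non-empty train and validation splits")
    x_tr, y_tr = _to_arrays(train_patches)
    x_va, y_va = _to_arrays(val_patches)
    t_tr, ig_tr = _targets(y_tr)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, lr=cfg.initial_lr)
    history: list[dict] = []
    best_acc, best_weights = -1.0, net.get_weights()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.minibatch):
            sel = order[i : i + cfg.minibatch]
            opt.zero_grad()
            logits = net.forward_logits(x_tr[sel])
            loss, dlogits = cross_entropy_loss(logits, t_tr[sel], ig_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, step {i // cfg.minibatch}"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = pixel_accuracy(net, x_va, y_va)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_pixel_accuracy": val_acc}
        )
        log.info("epoch %d: loss %.4f, val acc %.4f", epoch, history[-1]["train_loss"], val_acc)
        if val_acc > best_acc:
            best_acc, best_weights = val_acc, net.get_weights()
    net.set_weights(best_weights)
    return net, history


def evaluate_split(net: GraderNetwork, library: PatchLibrary, split: str = "test") -> float:
    patches = library.subset(split)
    if not patches:
        raise ValueError(f"split {split!r} is empty")
    x, y = _to_arrays(patches)
    return pixel_accuracy(net, x, y)


def predict_probabilities(net: GraderNetwork, rgb_batch: np.ndarray) -> np.ndarray:
    """(N,H,W,3) uint8 -> (N,H,W,C) per-pixel probabilities."""
    x = rgb_batch.astype(np.float32) / 255.0 - 0.5
    probs = softmax_channels(net.forward_logits(x.transpose(0, 3, 1, 2)))
    return probs.transpose(0, 2, 3, 1)
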