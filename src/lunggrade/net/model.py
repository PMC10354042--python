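"""The per-pixel six-class grading network.

Architecture: a residual encoder with ReLU-only pre-activation blocks, an
atrous (dilated) context convolution followed by an atrous spatial pyramid
pooling stage (parallel dilated 3x3 branches whose concatenation is pooled
by the next 1x1 convolution), and a transposed-convolution decoder that
expands the latent features back to input resolution before the six-way
per-pixel classifier.  A 3x3 kernel at dilation rate 4 spans an effective
11x11 region, so the pyramid sees progressively wider context without
losing resolution.

Two presets exist: ``faithful`` mirrors the published stage widths
(64/128/256/512), ``desk`` shrinks widths and depth so training runs in
minutes on one CPU.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import Conv2d, ConvTranspose2d, Param, PreActResidualBlock, ReLU, softmax_channels

CHECKPOINT_VERSION = 1


@dataclass
class NetworkSpec:
    """Hyperparameters of the grader network."""

    encoder_depth: int = 2  # residual stages; total downsampling is 2**depth
    base_width: int = 8
    aspp_rates: tuple[int, ...] = (2, 4, 8)
    atrous_rate: int = 4
    n_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth < 1 or self.base_width < 1 or self.n_classes < 2:
            raise ValueError("invalid network spec")
        if any(r < 1 for r in self.aspp_rates) or self.atrous_rate < 1:
            raise ValueError("dilation rates must be >= 1")


def faithful_spec(seed: int = 0) -> NetworkSpec:
    """Published-scale preset (stage widths 64/128/256/512)."""
    return NetworkSpec(encoder_depth=4, base_width=64, seed=seed)


def desk_spec(seed: int = 0) -> NetworkSpec:
    """CPU-trainable preset for synthetic-texture benchmarks."""
    return NetworkSpec(encoder_depth=2, base_width=8, seed=seed)


class GraderNetwork:
    """Fully-convolutional per-pixel classifier over the six target classes.

    The forward pass maps (H, W, 3) uint8 to (H, W, n_classes) softmax
    probabilities; H and W must be divisible by ``2**encoder_depth``.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.base_width
        widths = [w * 2**i for i in range(spec.encoder_depth)]
        self.stem = Conv2d(3, widths[0], 3, stride=2, rng=rng)
        self.encoder: list = []
        for i, ww in enumerate(widths):
            self.encoder.append(PreActResidualBlock(ww, rng))
            if i < len(widths) - 1:
                self.encoder.append(Conv2d(ww, widths[i + 1], 3, stride=2, rng=rng))
        top = widths[-1]
        # Atrous "rate" counts skipped pixels between samples (a rate-4 3x3
        # kernel spans 11x11), i.e. standard dilation = rate + 1.
        self.atrous = Conv2d(top, top, 3, dilation=spec.atrous_rate + 1, rng=rng)
        self.atrous_relu = ReLU()
        self.aspp = [Conv2d(top, w, 3, dilation=r + 1, rng=rng) for r in spec.aspp_rates]
        self.aspp_relu = ReLU()
        self.aspp_pool = Conv2d(w * len(spec.aspp_rates), top, 1, rng=rng)
        self.deconv = ConvTranspose2d(top, w, stride=2**spec.encoder_depth, rng=rng)
        self.dec_relu1 = ReLU()
        self.dec_conv = Conv2d(w, w, 3, rng=rng)
        self.dec_relu2 = ReLU()
        self.head = Conv2d(w, spec.n_classes, 1, rng=rng)
        self._modules = (
            [self.stem]
            + self.encoder
            + [self.atrous]
            + self.aspp
            + [self.aspp_pool, self.deconv, self.dec_conv, self.head]
        )

    @property
    def params(self) -> list[Param]:
        return [p for m in self._modules for p in m.params]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def _check_shape(self, x: np.ndarray) -> None:
        d = 2**self.spec.encoder_depth
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(f"input height/width must be divisible by {d}")

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """(N,3,H,W) float input in [-0.5, 0.5] -> (N,C,H,W) logits."""
        self._check_shape(x)
        h = self.stem.forward(x)
        for m in self.encoder:
            h = m.forward(h)
        h = self.atrous_relu.forward(self.atrous.forward(h))
        branches = [m.forward(h) for m in self.aspp]
        cat = self.aspp_relu.forward(np.concatenate(branches, axis=1))
        self._aspp_widths = [b.shape[1] for b in branches]
        h = self.aspp_pool.forward(cat)
        h = self.dec_relu1.forward(self.deconv.forward(h))
        h = self.dec_relu2.forward(self.dec_conv.forward(h))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dec_conv.backward(self.dec_relu2.backward(self.head.backward(dlogits)))
        d = self.deconv.backward(self.dec_relu1.backward(d))
        d = self.aspp_relu.backward(self.aspp_pool.backward(d))
        splits = np.cumsum(self._aspp_widths)[:-1]
        parts = np.split(d, splits, axis=1)
        d = sum(m.backward(p) for m, p in zip(self.aspp, parts))
        d = self.atrous.backward(self.atrous_relu.backward(d))
        for m in reversed(self.encoder):
            d = m.backward(d)
        self.stem.backward(d)

    # -- inference -----------------------------------------------------

    @staticmethod
    def _prep(rgb: np.ndarray) -> np.ndarray:
        x = np.asarray(rgb, dtype=np.float32) / 255.0 - 0.5
        return x.transpose(2, 0, 1)[None]

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (H, W, n_classes) for one RGB patch."""
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) patch, got {patch.shape}")
        logits = self.forward_logits(self._prep(patch))
        return softmax_channels(logits)[0].transpose(1, 2, 0)

    # -- checkpointing -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file archive: JSON spec + weight tensors, version-stamped."""
        spec = asdict(self.spec)
        spec["aspp_rates"] = list(spec["aspp_rates"])
        meta = {"version": CHECKPOINT_VERSION, "spec": spec}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("spec.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **{f"p{i}": p.value for i, p in enumerate(self.params)})
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "GraderNetwork":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("spec.json"))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            spec = meta["spec"]
            spec["aspp_rates"] = tuple(spec["aspp_rates"])
            net = cls(NetworkSpec(**spec))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as w:
                for i, p in enumerate(net.params):
                    p.value[...] = w[f"p{i}"]
        return net

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w


def build_network(spec: NetworkSpec | None = None) -> GraderNetwork:
    """Construct a grader network from a spec (desk preset by default)."""
    return GraderNetwork(spec or desk_spec())


def effective_span(kernel: int, rate: int) -> int:
    """Receptive span of an atrous kernel whose rate counts skipped pixels:
    (rate+1)*(kernel-1) + 1, so a 3x3 kernel at rate 4 spans 11x11."""
    return (rate + 1) * (kernel - 1) + 1
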