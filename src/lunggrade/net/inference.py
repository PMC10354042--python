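"""Whole-slide inference with overlap averaging and edge smoothing.

Slides are graded by overlapping-tile inference (default stride half the
tile), averaging per-pixel class probabilities across overlaps, followed by
a modal filter of the argmax raster — both steps target classification
artifacts at image-patch edges.  The classifier itself never produces
Background: pixels whose optical-density norm falls below a floor are
masked to Background afterwards (non-tissue).
"""

from __future__ import annotations

import numpy as np

from ..stain import rgb_to_od
from ..types import REFERENCE_MPP, ClassLabel, GradeMap
from .model import GraderNetwork
from .train import predict_probabilities


def tissue_mask(image: np.ndarray, od_floor: float = 0.15) -> np.ndarray:
    """Pixels with OD norm above the floor are tissue."""
    od = rgb_to_od(image).od
    return np.linalg.norm(od, axis=2) > od_floor


def modal_filter(labels: np.ndarray, window: int) -> np.ndarray:
    """Window-wise modal (majority) filter of a small-integer raster."""
    if window <= 1:
        return labels
    from scipy import ndimage

    n_classes = int(labels.max()) + 1
    votes = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for k in range(n_classes):
        votes[k] = ndimage.uniform_filter((labels == k).astype(np.float32), size=window)
    return votes.argmax(axis=0).astype(labels.dtype)


def grade_slide(
    net: GraderNetwork,
    image: np.ndarray,
    stride: int = 112,
    smooth_window: int = 5,
    tile: int = 224,
    od_floor: float = 0.15,
    microns_per_pixel: float = REFERENCE_MPP,
    batch: int = 8,
) -> GradeMap:
    """Grade a whole slide; output is congruent with the input.

    The image is expected at the reference resolution (resample upstream
    otherwise).  Tiles overlap by ``tile - stride`` pixels and their
    probabilities are averaged; the argmax raster is then modal-filtered
    over ``smooth_window`` and non-tissue pixels are set to Background.
    """
    if stride > tile:
        raise ValueError("stride must not exceed the tile size")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB slide")
    H, W = image.shape[:2]
    pad_r, pad_c = max(tile - H, 0), max(tile - W, 0)
    padded = (
        np.pad(image, ((0, pad_r), (0, pad_c), (0, 0)), mode="symmetric")
        if (pad_r or pad_c)
        else image
    )
    Hp, Wp = padded.shape[:2]

    def origins(extent: int) -> list[int]:
        out = list(range(0, extent - tile + 1, stride))
        if out[-1] != extent - tile:
            out.append(extent - tile)
        return out

    prob_sum = np.zeros((Hp, Wp, net.spec.n_classes), dtype=np.float32)
    weight = np.zeros((Hp, Wp), dtype=np.float32)
    coords = [(r, c) for r in origins(Hp) for c in origins(Wp)]
    for i in range(0, len(coords), batch):
        chunk = coords[i : i + batch]
        tiles = np.stack([padded[r : r + tile, c : c + tile] for r, c in chunk])
        probs = predict_probabilities(net, tiles)
        for (r, c), p in zip(chunk, probs):
            prob_sum[r : r + tile, c : c + tile] += p
            weight[r : r + tile, c : c + tile] += 1.0
    probs = prob_sum / weight[..., None]
    pred = probs.argmax(axis=2).astype(np.uint8) + 1  # class index -> ClassLabel
    pred = pred[:H, :W]
    pred = modal_filter(pred, smooth_window)
    pred[~tissue_mask(image, od_floor)] = int(ClassLabel.BACKGROUND)
    return GradeMap(labels=pred, microns_per_pixel=microns_per_pixel)
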