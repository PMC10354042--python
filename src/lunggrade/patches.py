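"""Patch-library construction from annotated slides.

Annotated slides are tiled into 224x224-pixel patches (112x112 µm at the
reference resolution), grouped by the modal annotated class within each
patch, selected up to a per-class quota, split 60/20/20 into train /
validation / test with every slide confined to a single split, and
area-balanced by appending geometrically augmented copies of patches whose
dominant class is underrepresented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .types import REFERENCE_MPP, ClassLabel, TARGET_CLASSES

log = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test")

# Tie-break priority for the dominant class: higher grade first (do not
# dilute rare high-grade patches), then airway over alveoli.
_PRIORITY = (
    ClassLabel.GRADE4,
    ClassLabel.GRADE3,
    ClassLabel.GRADE2,
    ClassLabel.GRADE1,
    ClassLabel.NORMAL_AIRWAY,
    ClassLabel.NORMAL_ALVEOLI,
)


@dataclass
class LabelMask:
    """Per-pixel class annotations paired with an RGB slide."""

    labels: np.ndarray
    microns_per_pixel: float = REFERENCE_MPP

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")


@dataclass
class Patch:
    rgb: np.ndarray  # (size, size, 3) uint8
    labels: np.ndarray  # (size, size) uint8
    slide_id: str
    origin: tuple[int, int]  # (row, col) of top-left pixel, 0-based
    dominant_class: ClassLabel
    augmented: bool = False


def dominant_class(labels: np.ndarray) -> ClassLabel:
    """Modal non-Background class of a label raster.

    Ties break toward the higher grade, then airway over alveoli;
    all-Background rasters return Background.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label raster")
    counts = np.bincount(labels.ravel(), minlength=7)
    best, best_count = ClassLabel.BACKGROUND, 0
    for cls in _PRIORITY:  # priority order resolves ties
        if counts[int(cls)] > best_count:
            best, best_count = cls, counts[int(cls)]
    return best


def tile_slide(
    image: np.ndarray,
    mask: LabelMask,
    size: int = 224,
    stride: int = 224,
    slide_id: str = "slide",
) -> list[Patch]:
    """Tile a slide and its mask into patches covering every pixel.

    Right/bottom remainders are reflection-padded on the image; padded
    label pixels are Background so they never vote for a class and are
    ignored in training.
    """
    if size < 1 or stride < 1:
        raise ValueError("size and stride must be >= 1")
    image = np.asarray(image)
    if image.shape[:2] != mask.labels.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.labels.shape} are not congruent"
        )
    H, W = mask.labels.shape
    origins_r = list(range(0, max(H - size, 0) + 1, stride))
    if origins_r[-1] + size < H:
        origins_r.append(H - size if H >= size else 0)
    origins_c = list(range(0, max(W - size, 0) + 1, stride))
    if origins_c[-1] + size < W:
        origins_c.append(W - size if W >= size else 0)

    pad_r, pad_c = max(size - H, 0), max(size - W, 0)
    if pad_r or pad_c:
        mode = "reflect" if pad_r < H and pad_c < W else "symmetric"
        image = np.pad(image, ((0, pad_r), (0, pad_c), (0, 0)), mode=mode)
        labels_pad = np.pad(mask.labels, ((0, pad_r), (0, pad_c)), constant_values=0)
    else:
        labels_pad = mask.labels

    out = []
    for r in origins_r:
        for c in origins_c:
            rgb = image[r : r + size, c : c + size]
            lab = labels_pad[r : r + size, c : c + size]
            if rgb.shape[0] < size or rgb.shape[1] < size:  # interior remainder
                rgb = np.pad(
                    rgb,
                    ((0, size - rgb.shape[0]), (0, size - rgb.shape[1]), (0, 0)),
                    mode="reflect",
                )
                lab = np.pad(
                    lab,
                    ((0, size - lab.shape[0]), (0, size - lab.shape[1])),
                    constant_values=0,
                )
            out.append(
                Patch(
                    rgb=np.ascontiguousarray(rgb),
                    labels=np.ascontiguousarray(lab),
                    slide_id=slide_id,
                    origin=(r, c),
                    dominant_class=dominant_class(lab),
                )
            )
    return out


@dataclass
class PatchLibrary:
    """Patches with their split assignment and per-split class-area tallies."""

    patches: list[Patch] = field(default_factory=list)
    split: list[str] = field(default_factory=list)  # aligned with patches
    slide_split: dict[str, str] = field(default_factory=dict)

    def subset(self, split: str) -> list[Patch]:
        return [p for p, s in zip(self.patches, self.split) if s == split]

    def class_area(self, split: str | None = None) -> dict[ClassLabel, int]:
        """Per-class pixel tallies (target classes only)."""
        tally = np.zeros(7, dtype=np.int64)
        for p, s in zip(self.patches, self.split):
            if split is None or s == split:
                tally += np.bincount(p.labels.ravel(), minlength=7)
        return {cls: int(tally[int(cls)]) for cls in TARGET_CLASSES}

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "slide_id": p.slide_id,
                "origin_row": p.origin[0],
                "origin_col": p.origin[1],
                "dominant_class": p.dominant_class.name,
                "split": s,
                "augmented": p.augmented,
            }
            for p, s in zip(self.patches, self.split)
        ]
        return pd.DataFrame(rows)


def _assign_slide_splits(
    slide_stats: dict[str, int], fractions: tuple[float, float, float], rng: np.random.Generator
) -> dict[str, str]:
    """Greedy slide-to-split assignment approximating the target fractions
    by annotated area (largest slides placed first, seeded shuffle on ties)."""
    ids = list(slide_stats)
    rng.shuffle(ids)
    ids.sort(key=lambda s: -slide_stats[s])
    total = sum(slide_stats.values()) or 1
    target = {s: f * total for s, f in zip(SPLITS, fractions)}
    current = {s: 0.0 for s in SPLITS}
    assignment = {}
    for i, sid in enumerate(ids):
        if i < 3:  # guarantee each split holds at least one slide
            split = SPLITS[i]
        else:
            split = min(SPLITS, key=lambda s: current[s] / max(target[s], 1e-9))
        assignment[sid] = split
        current[split] += slide_stats[sid]
    return assignment


def build_library(
    slides: list[tuple[np.ndarray, LabelMask]],
    quota_per_class: int = 6000,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    size: int = 224,
    stride: int | None = None,
    slide_ids: list[str] | None = None,
) -> PatchLibrary:
    """Build the patch library: tile, group by dominant class, select up to
    the per-class quota, with slide-disjoint splits assigned up front."""
    if len(slides) < 3:
        raise ValueError("need at least 3 slides (one per split)")
    if not np.isclose(sum(split_fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    stride = stride or size
    slide_ids = slide_ids or [f"slide{i:03d}" for i in range(len(slides))]

    all_patches: list[Patch] = []
    slide_stats: dict[str, int] = {}
    for sid, (image, mask) in zip(slide_ids, slides):
        ps = tile_slide(image, mask, size=size, stride=stride, slide_id=sid)
        ps = [p for p in ps if p.dominant_class != ClassLabel.BACKGROUND]
        all_patches.extend(ps)
        slide_stats[sid] = int(np.count_nonzero(mask.labels))

    assignment = _assign_slide_splits(slide_stats, split_fractions, rng)

    lib = PatchLibrary(slide_split=assignment)
    for cls in TARGET_CLASSES:
        group = [p for p in all_patches if p.dominant_class == cls]
        if not group:
            log.warning("class %s has no available patches", cls.name)
            continue
        if len(group) > quota_per_class:
            chosen = rng.choice(len(group), size=quota_per_class, replace=False)
            group = [group[i] for i in sorted(chosen)]
        else:
            if quota_per_class > len(group):
                log.info(
                    "class %s: quota %d exceeds supply %d; using all",
                    cls.name, quota_per_class, len(group),
                )
        for p in group:
            lib.patches.append(p)
            lib.split.append(assignment[p.slide_id])
    return lib


def augment_patch(patch: Patch, rng: np.random.Generator) -> Patch:
    """One random geometric augmentation: translation (<= a quarter of the
    patch, i.e. 56 px at the default 224, reflection fill), shear (<= 10°)
    and rotation (90/180/270° ± 10°), applied jointly to the image and the
    label raster (nearest-neighbor labels)."""
    size = patch.labels.shape[0]
    angle = np.deg2rad(rng.choice([90, 180, 270]) + rng.uniform(-10, 10))
    shear = np.deg2rad(rng.uniform(-10, 10))
    max_shift = min(56, size // 4)
    trans = rng.uniform(-max_shift, max_shift, size=2)
    center = (size - 1) / 2.0
    t = (
        sktransform.AffineTransform(translation=(-center, -center))
        + sktransform.AffineTransform(rotation=angle, shear=shear)
        + sktransform.AffineTransform(translation=(center + trans[0], center + trans[1]))
    )
    rgb = sktransform.warp(
        patch.rgb.astype(float), t.inverse, order=1, mode="reflect", preserve_range=True
    ).astype(np.uint8)
    labels = sktransform.warp(
        patch.labels.astype(float), t.inverse, order=0, mode="reflect", preserve_range=True
    ).astype(np.uint8)
    return Patch(
        rgb=rgb,
        labels=labels,
        slide_id=patch.slide_id,
        origin=patch.origin,
        dominant_class=dominant_class(labels),
        augmented=True,
    )


def balance_by_area(
    library: PatchLibrary,
    tolerance: float = 0.05,
    seed: int = 0,
    max_copies_per_split: int = 800,
) -> PatchLibrary:
    """Equalize per-class pixel area within each split by appending
    augmented copies of patches dominated by the deficient class.

    Originals are retained; a deficient class with no source patches is
    left unbalanced with a warning.  Convergence is best-effort under the
    copy cap.
    """
    if not library.patches:
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    out = PatchLibrary(
        patches=list(library.patches),
        split=list(library.split),
        slide_split=dict(library.slide_split),
    )

    def tally(patch: Patch) -> np.ndarray:
        return np.bincount(patch.labels.ravel(), minlength=7)

    for split in SPLITS:
        in_split = [p for p, s in zip(library.patches, library.split) if s == split]
        if not in_split:
            continue
        # Sources per class, sorted purest-first: appending near-pure copies
        # raises the deficient class faster than the majority class, which
        # is what makes the loop converge.
        sources: dict[ClassLabel, list[Patch]] = {}
        for cls in TARGET_CLASSES:
            cands = [p for p in in_split if p.dominant_class == cls]
            cands.sort(key=lambda p: -tally(p)[int(cls)])
            sources[cls] = cands
        area = np.sum([tally(p) for p in in_split], axis=0)
        warned: set[ClassLabel] = set()
        hopeless: set[ClassLabel] = set()
        last_ratio: dict[ClassLabel, float] = {}
        for _ in range(max_copies_per_split):
            class_area = {c: int(area[int(c)]) for c in TARGET_CLASSES}
            max_area = max(class_area.values())
            if max_area == 0:
                break
            deficient = sorted(
                (c for c, a in class_area.items() if a < (1 - tolerance) * max_area),
                key=lambda c: class_area[c],
            )
            todo = None
            for c in deficient:
                if c in hopeless:
                    continue
                if sources[c]:
                    todo = c
                    break
                if c not in warned and class_area[c] > 0:
                    log.warning(
                        "split %s: class %s deficient but has no source patches",
                        split, c.name,
                    )
                    warned.add(c)
            if todo is None:
                break
            cands = sources[todo]
            src = cands[rng.integers(max(len(cands) // 4, 1))]
            aug = augment_patch(src, rng)
            out.patches.append(aug)
            out.split.append(split)
            area = area + tally(aug)
            # Stall detection: sources too impure to ever reach tolerance.
            max_c = max(TARGET_CLASSES, key=lambda c: area[int(c)])
            ratio = float(area[int(todo)]) / max(float(area[int(max_c)]), 1.0)
            if ratio <= last_ratio.get(todo, -1.0) + 1e-3:
                hopeless.add(todo)
                log.warning(
                    "split %s: class %s left unbalanced (sources too impure)",
                    split, todo.name,
                )
            last_ratio[todo] = ratio
    return out


def save_library(library: PatchLibrary, directory: str | Path) -> None:
    """Write patches as paired PNGs plus a CSV manifest."""
    from . import io as lio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(library.patches):
        lio.write_rgb(directory / f"patch{i:06d}_rgb.png", p.rgb)
        lio.write_labels(directory / f"patch{i:06d}_labels.png", p.labels)
    library.manifest().to_csv(directory / "manifest.csv", index=False)


def load_library(directory: str | Path) -> PatchLibrary:
    from . import io as lio

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    lib = PatchLibrary()
    for i, row in manifest.iterrows():
        rgb = lio.read_rgb(directory / f"patch{i:06d}_rgb.png")
        labels = lio.read_labels(directory / f"patch{i:06d}_labels.png")
        lib.patches.append(
            Patch(
                rgb=rgb,
                labels=labels,
                slide_id=row["slide_id"],
                origin=(int(row["origin_row"]), int(row["origin_col"])),
                dominant_class=ClassLabel[row["dominant_class"]],
                augmented=bool(row.get("augmented", False)),
            )
        )
        lib.split.append(row["split"])
        lib.slide_split[row["slide_id"]] = row["split"]
    return lib
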