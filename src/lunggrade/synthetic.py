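"""Deterministic synthetic-histology generators for testing the pipeline.

Every module in the package is testable without any downloaded data: this
module renders class-textured H&E-like slides with exact ground-truth label
masks, DAB-like IHC point patterns with known cell lists, and the bundled
rater-agreement count table.

The textures are engineered to be easily separable — each class has a
distinct hematoxylin/eosin mixture and spatial motif — so that desk-scale
network benchmarks exercise the pipeline rather than representational
capacity.  Rendering goes through the same stain matrices the analysis
modules use for unmixing, making the detection oracles exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ihc import CellRecord
from .stain import HDAB_STAIN_MATRIX, HE_REFERENCE, od_to_rgb
from .types import ClassLabel, GradeMap

# Base hematoxylin/eosin concentrations per class (base-10 OD scale).
# Hematoxylin rises strictly with grade (nuclear density/crowding); eosin
# falls as cytoplasm is displaced.
_CLASS_HE = {
    ClassLabel.NORMAL_ALVEOLI: (0.06, 0.18),
    ClassLabel.NORMAL_AIRWAY: (0.14, 0.36),
    ClassLabel.GRADE1: (0.20, 0.50),
    ClassLabel.GRADE2: (0.36, 0.42),
    ClassLabel.GRADE3: (0.52, 0.30),
    ClassLabel.GRADE4: (0.68, 0.16),
}


def _smooth_noise(shape, rng: np.random.Generator, sigma: float = 3.0) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return n / s if s > 0 else n


def _he_fields(cls: ClassLabel, shape: tuple[int, int], rng: np.random.Generator):
    """Hematoxylin/eosin concentration fields for one class."""
    h0, e0 = _CLASS_HE[cls]
    h = np.full(shape, h0) + 0.025 * _smooth_noise(shape, rng)
    e = np.full(shape, e0) + 0.02 * _smooth_noise(shape, rng)
    rows, cols = np.indices(shape)
    if cls == ClassLabel.NORMAL_ALVEOLI:
        # Sparse lattice of thin eosinophilic septa with occasional nuclei.
        period = 14
        walls = ((rows % period) < 2) | ((cols % period) < 2)
        e = np.where(walls, e + 0.22, e)
        h = np.where(walls, h + 0.06, h)
        dots = rng.random(shape) < 0.002
        h = np.where(ndimage.binary_dilation(dots), h + 0.30, h)
    elif cls == ClassLabel.NORMAL_AIRWAY:
        # Concentric ring motif (airway wall) around a per-tile center.
        cy, cx = rng.uniform(0.3, 0.7, 2) * np.array(shape)
        rad = np.hypot(rows - cy, cols - cx)
        rings = 0.5 * (1 + np.sin(rad / 4.0))
        e = e + 0.18 * rings
        h = h + 0.12 * (rings > 0.8)
    else:
        # Tumor grades: nuclear stippling whose density rises with grade.
        density = 0.004 + 0.004 * (cls.grade_number - 1)
        dots = rng.random(shape) < density
        h = np.where(ndimage.binary_dilation(dots), h + 0.10, h)
    return np.clip(h, 0.02, None), np.clip(e, 0.02, None)


def make_texture_tile(cls: ClassLabel, size: int, seed: int) -> np.ndarray:
    """Render one class texture tile as an RGB raster (deterministic)."""
    if cls == ClassLabel.BACKGROUND:
        raise ValueError("Background has no texture")
    rng = np.random.default_rng(seed)
    h, e = _he_fields(cls, (size, size), rng)
    od = np.stack([h, e], axis=-1) @ HE_REFERENCE.stain_matrix.T
    return od_to_rgb(od)


@dataclass
class TumorBlobSpec:
    """One tumor blob: circle with an angular grade partition."""

    center: tuple[int, int]  # (row, col)
    radius: int
    composition: dict[int, float]  # grade number -> area fraction, sums to 1


@dataclass
class SlideLayoutSpec:
    """Layout of a synthetic slide: lung ellipse, airways, tumor blobs."""

    canvas_size: tuple[int, int] = (448, 448)
    background_white: int = 255
    lung_center: tuple[int, int] | None = None
    lung_radii: tuple[int, int] | None = None
    airways: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    tumor_blobs: list[TumorBlobSpec] = field(default_factory=list)
    seed: int = 0


def make_synthetic_slide(spec: SlideLayoutSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide and its ground-truth label mask.

    The lung ellipse is alveolar texture; airways are ring-textured discs;
    each tumor blob is a disc partitioned by angle into grade sectors
    matching its composition (later blobs win on overlap).  Returns
    ``(rgb, labels)`` with congruent shapes.
    """
    H, W = spec.canvas_size
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros((H, W), dtype=np.uint8)
    rows, cols = np.indices((H, W))

    lc = spec.lung_center or (H // 2, W // 2)
    lr = spec.lung_radii or (int(H * 0.45), int(W * 0.45))
    lung = ((rows - lc[0]) / lr[0]) ** 2 + ((cols - lc[1]) / lr[1]) ** 2 <= 1.0
    labels[lung] = int(ClassLabel.NORMAL_ALVEOLI)

    for (cr, cc), rad in spec.airways:
        disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2
        labels[disc & lung] = int(ClassLabel.NORMAL_AIRWAY)

    for blob in spec.tumor_blobs:
        total = sum(blob.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("blob composition must sum to 1")
        cr, cc = blob.center
        disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= blob.radius**2
        disc &= lung
        theta = np.arctan2(rows - cr, cols - cc)  # [-pi, pi]
        # Deterministic angular partition proportional to composition.
        start = -np.pi
        for grade in sorted(blob.composition):
            frac = blob.composition[grade]
            end = start + 2 * np.pi * frac
            sector = disc & (theta >= start - 1e-12) & (theta < end)
            labels[sector] = int(ClassLabel.GRADE1) + grade - 1
            start = end
        # Sweep rounding: assign any leftover disc pixels to the last grade.
        leftover = disc & (theta >= start - 1e-12)
        labels[leftover] = int(ClassLabel.GRADE1) + max(blob.composition) - 1

    rgb = np.full((H, W, 3), spec.background_white, dtype=np.uint8)
    for cls in _CLASS_HE:
        mask = labels == int(cls)
        if not mask.any():
            continue
        tile = make_texture_tile(cls, max(H, W), seed=int(rng.integers(2**31)))
        rgb[mask] = tile[:H, :W][mask]
    return rgb, labels


def random_slide_spec(
    seed: int,
    canvas_size: tuple[int, int] = (448, 448),
    n_tumors: int = 4,
    tumor_radius: tuple[int, int] = (40, 70),
    mixed_fraction: float = 0.5,
) -> SlideLayoutSpec:
    """A randomized but reproducible slide layout covering all six classes."""
    rng = np.random.default_rng(seed)
    H, W = canvas_size
    lc, lr = (H // 2, W // 2), (int(H * 0.47), int(W * 0.47))
    airways = []
    for _ in range(3):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.55)
        airways.append(
            (
                (
                    int(lc[0] + rad * lr[0] * np.sin(ang)),
                    int(lc[1] + rad * lr[1] * np.cos(ang)),
                ),
                int(rng.integers(28, 46)),
            )
        )
    blobs = []
    for i in range(n_tumors):
        radius = int(rng.integers(*tumor_radius))
        # Rejection-sample centers so blobs stay disjoint (segmenting the
        # mask must recover exactly the specified blob count).
        center = None
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.1, 0.6)
            cand = (
                int(lc[0] + rad * lr[0] * np.sin(ang)),
                int(lc[1] + rad * lr[1] * np.cos(ang)),
            )
            if all(
                np.hypot(cand[0] - b.center[0], cand[1] - b.center[1]) > radius + b.radius + 6
                for b in blobs
            ):
                center = cand
                break
        if center is None:
            break  # canvas full; fewer blobs than requested
        # First four blobs cycle the pure grades so every slide covers all
        # four; extras are random mixed-grade mosaics.
        if i < 4:
            comp = {i % 4 + 1: 1.0}
        elif rng.random() < mixed_fraction:
            grades = sorted(rng.choice([1, 2, 3, 4], size=2, replace=False).tolist())
            f = float(rng.uniform(0.3, 0.7))
            comp = {grades[0]: f, grades[1]: 1.0 - f}
        else:
            comp = {int(rng.integers(1, 5)): 1.0}
        blobs.append(TumorBlobSpec(center=center, radius=radius, composition=comp))
    return SlideLayoutSpec(
        canvas_size=canvas_size,
        lung_center=lc,
        lung_radii=lr,
        airways=airways,
        tumor_blobs=blobs,
        seed=seed,
    )


@dataclass
class IHCPatternSpec:
    """Parameters of a DAB-like point pattern over a grade map.

    ``cell_density`` is cells per mm²; positivity of a cell is a Bernoulli
    draw with probability ``baseline_positive_fraction`` times the
    enrichment multiplier of the grade at its location (clipped to [0, 1]).
    """

    cell_density: float = 4000.0
    baseline_positive_fraction: float = 0.15
    enrichment: dict[int, float] = field(default_factory=dict)  # grade -> multiplier
    nucleus_radius: int = 3
    min_separation: float | None = None  # defaults to 2.5 x nucleus_radius
    seed: int = 0


def make_ihc_pattern(
    grade_map: GradeMap, spec: IHCPatternSpec
) -> tuple[np.ndarray, list[CellRecord]]:
    """Render an IHC-like image over the tissue of ``grade_map``.

    Cells are placed by seeded random sampling within tissue with a minimum
    separation (dart throwing); positives get a DAB-brown disk on top of
    the hematoxylin-blue nucleus.  Returns the rendered RGB image and the
    ground-truth cell list (IHC-frame centroids and positivity).
    """
    if spec.cell_density <= 0:
        raise ValueError("cell density must be positive")
    rng = np.random.default_rng(spec.seed)
    H, W = grade_map.shape
    tissue = grade_map.tissue_mask()
    mpp = grade_map.microns_per_pixel
    area_mm2 = tissue.sum() * (mpp / 1000.0) ** 2
    n_target = int(round(spec.cell_density * area_mm2))
    sep = spec.min_separation or 2.5 * spec.nucleus_radius

    tissue_idx = np.flatnonzero(tissue.ravel())
    order = rng.permutation(tissue_idx)
    # Grid-hash dart throwing for the minimum separation.
    cell_size = max(sep, 1.0)
    grid: dict[tuple[int, int], list[tuple[int, int]]] = {}
    placed: list[tuple[int, int]] = []
    for flat in order:
        if len(placed) >= n_target:
            break
        r, c = divmod(int(flat), W)
        gk = (int(r / cell_size), int(c / cell_size))
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for pr, pc in grid.get((gk[0] + dr, gk[1] + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((r, c))
            grid.setdefault(gk, []).append((r, c))

    cells: list[CellRecord] = []
    h_conc = np.zeros((H, W))
    dab_conc = np.zeros((H, W))
    rad = spec.nucleus_radius
    rr, cc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disk = ((rr**2 + cc**2) <= rad**2).astype(float)
    for r, c in placed:
        label = ClassLabel(int(grade_map.labels[r, c]))
        mult = spec.enrichment.get(label.grade_number, 1.0) if label.is_grade else 1.0
        p_pos = float(np.clip(spec.baseline_positive_fraction * mult, 0.0, 1.0))
        positive = bool(rng.random() < p_pos)
        cells.append(CellRecord(centroid_ihc=(float(r), float(c)), positive=positive))
        r0, r1 = max(r - rad, 0), min(r + rad + 1, H)
        c0, c1 = max(c - rad, 0), min(c + rad + 1, W)
        d = disk[
            r0 - (r - rad) : disk.shape[0] - ((r + rad + 1) - r1),
            c0 - (c - rad) : disk.shape[1] - ((c + rad + 1) - c1),
        ]
        h_conc[r0:r1, c0:c1] += 0.45 * d
        if positive:
            dab_conc[r0:r1, c0:c1] += 0.55 * d
    # Faint tissue wash so the section outline is visible to registration.
    h_conc += np.where(tissue, 0.06, 0.0)
    od = np.stack([h_conc, dab_conc], axis=-1) @ HDAB_STAIN_MATRIX.T
    return od_to_rgb(od), cells


def table1_fixture():
    """The bundled published rater-agreement count table.

    Rows: automated call (Normal, Grades 1-4); columns: manual grade
    (Grades 1-4); n = 1958 manually segmented tumors across 10 slides.
    """
    from .evaluation import ConfusionMatrix

    counts = np.array(
        [
            [26, 0, 0, 0],
            [649, 66, 12, 0],
            [56, 322, 40, 1],
            [23, 53, 690, 2],
            [0, 0, 2, 16],
        ],
        dtype=np.int64,
    )
    return ConfusionMatrix(
        categories_rows=["Normal", "Grade 1", "Grade 2", "Grade 3", "Grade 4"],
        categories_cols=["Grade 1", "Grade 2", "Grade 3", "Grade 4"],
        counts=counts,
    )
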