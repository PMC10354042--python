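"""Core label taxonomy and raster containers shared across the pipeline.

The pixel taxonomy is seven-way: Background plus six target classes — the
two normal lung compartments (alveoli, airway) and the four LUAD grades
(Grade 1 lowest to Grade 4 highest, the mouse grading scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Reference scan resolution (a 20x slide scanner), microns per pixel.
REFERENCE_MPP = 0.5022


class ClassLabel(IntEnum):
    """Per-pixel class. Integer values double as the raster palette index."""

    BACKGROUND = 0
    NORMAL_ALVEOLI = 1
    NORMAL_AIRWAY = 2
    GRADE1 = 3
    GRADE2 = 4
    GRADE3 = 5
    GRADE4 = 6

    @property
    def is_grade(self) -> bool:
        return self >= ClassLabel.GRADE1

    @property
    def grade_number(self) -> int:
        """1-4 for tumor grades; raises for non-grade labels."""
        if not self.is_grade:
            raise ValueError(f"{self.name} is not a tumor grade")
        return int(self) - int(ClassLabel.GRADE1) + 1


#: The six classes the network predicts (everything except Background).
TARGET_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.NORMAL_ALVEOLI,
    ClassLabel.NORMAL_AIRWAY,
    ClassLabel.GRADE1,
    ClassLabel.GRADE2,
    ClassLabel.GRADE3,
    ClassLabel.GRADE4,
)

GRADE_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.GRADE1,
    ClassLabel.GRADE2,
    ClassLabel.GRADE3,
    ClassLabel.GRADE4,
)

#: Display palette for indexed label images (RGB, 0-255).
LABEL_PALETTE: dict[ClassLabel, tuple[int, int, int]] = {
    ClassLabel.BACKGROUND: (255, 255, 255),
    ClassLabel.NORMAL_ALVEOLI: (180, 220, 180),
    ClassLabel.NORMAL_AIRWAY: (120, 160, 220),
    ClassLabel.GRADE1: (255, 255, 160),
    ClassLabel.GRADE2: (255, 190, 120),
    ClassLabel.GRADE3: (240, 120, 80),
    ClassLabel.GRADE4: (170, 40, 40),
}


@dataclass
class GradeMap:
    """Per-pixel class-label raster with physical resolution.

    The central exchange object between grading, tumor analytics and IHC
    projection.  ``labels`` holds :class:`ClassLabel` values as uint8.
    """

    labels: np.ndarray
    microns_per_pixel: float = REFERENCE_MPP

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("GradeMap labels must be a 2-D raster")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def grade_mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying any tumor grade."""
        return self.labels >= int(ClassLabel.GRADE1)

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of non-Background pixels (lung tissue)."""
        return self.labels != int(ClassLabel.BACKGROUND)

    def pixel_area_um2(self) -> float:
        return self.microns_per_pixel**2


@dataclass
class TumorObject:
    """One connected tumor: a mosaic of grade pixels.

    ``composition`` holds the fraction of the tumor's graded area in each
    present grade (keys 1-4, values summing to 1).  ``overall_grade`` is
    assigned by the highest-grade-at-least-10% rule, ``sdi`` is the Shannon
    diversity of the composition in nats.
    """

    tumor_id: int
    pixel_mask: np.ndarray  # boolean raster, same frame as the GradeMap
    pixel_count: int
    area_um2: float
    grade_pixels: dict[int, int]  # grade number (1-4) -> pixel count
    composition: dict[int, float] = field(default_factory=dict)
    overall_grade: int = 0
    sdi: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (rmin, cmin, rmax, cmax) inclusive


def rgb_from_labels(labels: np.ndarray) -> np.ndarray:
    """Render an indexed label raster to RGB using the standard palette."""
    lut = np.zeros((256, 3), dtype=np.uint8)
    for cls, color in LABEL_PALETTE.items():
        lut[int(cls)] = color
    return lut[np.asarray(labels, dtype=np.uint8)]
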