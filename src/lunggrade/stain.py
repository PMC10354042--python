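"""Macenko stain-vector estimation and normalization of H&E images.

The working space is per-channel optical density (Beer-Lambert, base 10):
``OD = -log10(I / I0)`` with ``I0`` the background white level.  Stain
concentrations are linear in OD, so every pixel is a nonnegative mixture of
the two stain vectors (hematoxylin, eosin).  The Macenko estimator finds
those vectors as the extreme-percentile directions of tissue pixels
projected into the top-two singular plane of the OD cloud; normalization
re-expresses the image in a reference stain basis after matching each
stain's 99th-percentile concentration to the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DegenerateInputError(ValueError):
    """Too few tissue pixels to estimate a stain model."""


class CollinearityError(ValueError):
    """OD cloud is rank-1 (single stain / grayscale): no stain plane exists."""


@dataclass
class OpticalDensityImage:
    """Per-pixel 3-channel optical density plus the white level it came from."""

    od: np.ndarray  # (H, W, 3) float64, base-10 OD, >= 0
    source_white: np.ndarray  # per-channel I0, (3,)


@dataclass
class StainModel:
    """Two unit stain vectors in OD space plus per-stain reference scale.

    Columns of ``stain_matrix`` are hematoxylin then eosin; hematoxylin is
    identified as the column with the larger red-channel OD component
    (hematoxylin appears blue because it absorbs red light).
    ``max_concentration`` is the 99th-percentile concentration per stain.
    """

    stain_matrix: np.ndarray  # (3, 2), unit columns
    max_concentration: np.ndarray  # (2,)
    I0: np.ndarray = field(default_factory=lambda: np.array([255.0, 255.0, 255.0]))

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentration = np.asarray(self.max_concentration, dtype=float)
        self.I0 = np.asarray(self.I0, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            self.stain_matrix = self.stain_matrix / norms

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stain_matrix": self.stain_matrix.tolist(),
                    "max_concentration": self.max_concentration.tolist(),
                    "I0": self.I0.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainModel":
        d = json.loads(Path(path).read_text())
        return cls(
            stain_matrix=np.array(d["stain_matrix"]),
            max_concentration=np.array(d["max_concentration"]),
            I0=np.array(d["I0"]),
        )


def _he_reference() -> StainModel:
    # Widely used H&E reference stain vectors; concentrations on the
    # base-10 OD scale used throughout this module.
    m = np.array(
        [
            [0.5626, 0.2159],
            [0.7201, 0.8012],
            [0.4062, 0.5581],
        ]
    )
    return StainModel(stain_matrix=m, max_concentration=np.array([0.8558, 0.4477]))


#: Default reference stain profile used by :func:`normalize_to_reference`.
HE_REFERENCE: StainModel = _he_reference()


def _unit_cols(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0)


#: Standard hematoxylin + DAB unmixing vectors (columns H, DAB) in OD space,
#: used for IHC color deconvolution and for rendering synthetic IHC images.
HDAB_STAIN_MATRIX: np.ndarray = _unit_cols(
    np.array(
        [
            [0.650, 0.269],
            [0.704, 0.568],
            [0.286, 0.778],
        ]
    )
)


def rgb_to_od(image: np.ndarray, I0: float | np.ndarray = 255.0) -> OpticalDensityImage:
    """Convert an RGB raster to base-10 optical density.

    Pixels equal to ``I0`` map to OD 0; intensities are floored at 1 so the
    transform stays finite.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    I0 = np.broadcast_to(np.asarray(I0, dtype=float), (3,)).copy()
    if np.any(I0 <= 0):
        raise ValueError("white level I0 must be positive")
    od = -np.log10(np.maximum(image, 1.0) / I0)
    return OpticalDensityImage(od=np.maximum(od, 0.0), source_white=I0)


def od_to_rgb(od: np.ndarray, I0: float | np.ndarray = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od`; returns uint8 clipped to [0, 255]."""
    I0 = np.broadcast_to(np.asarray(I0, dtype=float), (3,))
    rgb = I0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def estimate_stain_model(
    od_image: OpticalDensityImage,
    alpha_percentile: float = 1.0,
    beta_od_floor: float = 0.15,
    min_tissue_pixels: int = 100,
) -> StainModel:
    """Macenko estimation of the two stain vectors and their scale.

    Tissue pixels (OD norm above ``beta_od_floor``) are projected onto the
    top-two singular plane of the OD cloud; the stain vectors are the
    ``alpha`` / ``100 - alpha`` percentile angular directions of those
    projections.  Concentrations are recovered by least squares and the
    99th percentile per stain is stored as the model's scale.
    """
    od = od_image.od.reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > beta_od_floor]
    if tissue.shape[0] < min_tissue_pixels:
        raise DegenerateInputError(
            f"only {tissue.shape[0]} tissue pixels above OD {beta_od_floor}; "
            f"need at least {min_tissue_pixels}"
        )

    # Plane of the OD cloud: top-2 right singular vectors.
    _, s, vt = np.linalg.svd(tissue, full_matrices=False)
    if s[1] <= 1e-4 * s[0]:
        raise CollinearityError("OD cloud is rank-1; cannot separate two stains")
    basis = vt[:2].T  # (3, 2)
    # Orient the basis so projections land in a consistent half-plane.
    for j in range(2):
        if basis[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]

    proj = tissue @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_lo = np.percentile(phi, alpha_percentile)
    phi_hi = np.percentile(phi, 100.0 - alpha_percentile)
    v_lo = basis @ np.array([np.cos(phi_lo), np.sin(phi_lo)])
    v_hi = basis @ np.array([np.cos(phi_hi), np.sin(phi_hi)])
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v *= -1

    # Hematoxylin first: larger red-channel absorbance.
    if v_lo[0] >= v_hi[0]:
        matrix = np.column_stack([v_lo, v_hi])
    else:
        matrix = np.column_stack([v_hi, v_lo])
    matrix = matrix / np.linalg.norm(matrix, axis=0)

    conc, *_ = np.linalg.lstsq(matrix, tissue.T, rcond=None)
    max_c = np.percentile(np.maximum(conc, 0.0), 99, axis=1)
    return StainModel(
        stain_matrix=matrix, max_concentration=max_c, I0=od_image.source_white
    )


def unmix_concentrations(od_image: OpticalDensityImage, model: StainModel) -> np.ndarray:
    """Per-pixel stain concentrations (H, W, 2) under ``model`` (least squares)."""
    h, w, _ = od_image.od.shape
    conc, *_ = np.linalg.lstsq(model.stain_matrix, od_image.od.reshape(-1, 3).T, rcond=None)
    return conc.T.reshape(h, w, 2)


def normalize_to_reference(
    image: np.ndarray,
    reference: StainModel | None = None,
    I0: float | np.ndarray = 255.0,
    alpha_percentile: float = 1.0,
    beta_od_floor: float = 0.15,
) -> np.ndarray:
    """Map an H&E image to the reference stain appearance.

    Source concentrations are rescaled so each stain's 99th percentile
    matches the reference ``max_concentration``, then re-composited with
    the reference stain matrix.
    """
    reference = HE_REFERENCE if reference is None else reference
    if np.any(reference.max_concentration <= 0):
        raise ValueError("reference max_concentration must be positive")
    od_image = rgb_to_od(image, I0=I0)
    source = estimate_stain_model(
        od_image, alpha_percentile=alpha_percentile, beta_od_floor=beta_od_floor
    )
    conc = unmix_concentrations(od_image, source)
    scale = reference.max_concentration / np.maximum(source.max_concentration, 1e-8)
    conc = np.maximum(conc, 0.0) * scale
    od_norm = conc.reshape(-1, 2) @ reference.stain_matrix.T
    return od_to_rgb(od_norm.reshape(od_image.od.shape), I0=reference.I0)
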