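"""Reading and writing the small set of on-disk formats the pipeline uses.

RGB slides and label rasters travel as 8-bit TIFF/PNG (tifffile / imageio);
label rasters are single-channel indexed images whose pixel values are the
:class:`~lunggrade.types.ClassLabel` integers.  GradeMaps carry a JSON
sidecar with the physical resolution.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import REFERENCE_MPP, GradeMap


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (TIFF or PNG) as an (H, W, 3) uint8 array."""
    path = Path(path)
    arr = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path} is not an RGB image (shape {arr.shape})")
    return np.ascontiguousarray(arr[..., :3], dtype=np.uint8)


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if _is_tiff(path):
        tifffile.imwrite(path, image, photometric="rgb")
    else:
        iio.imwrite(path, image)


def read_labels(path: str | Path) -> np.ndarray:
    """Read a single-channel indexed label raster as (H, W) uint8."""
    path = Path(path)
    arr = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # palette images may expand; take first channel
        arr = arr[..., 0]
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    path = Path(path)
    labels = np.asarray(labels, dtype=np.uint8)
    if _is_tiff(path):
        tifffile.imwrite(path, labels, photometric="minisblack")
    else:
        iio.imwrite(path, labels)


def write_grade_map(path: str | Path, grade_map: GradeMap, model_version: str = "dev") -> None:
    """Write the label raster plus a JSON sidecar with resolution metadata."""
    path = Path(path)
    write_labels(path, grade_map.labels)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"microns_per_pixel": grade_map.microns_per_pixel, "model_version": model_version}
        )
    )


def read_grade_map(path: str | Path) -> GradeMap:
    path = Path(path)
    labels = read_labels(path)
    mpp = REFERENCE_MPP
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        mpp = float(json.loads(sidecar.read_text())["microns_per_pixel"])
    return GradeMap(labels=labels, microns_per_pixel=mpp)
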