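"""End-to-end orchestration: slide in, grade map and tumor tables out.

``run_pipeline`` grades each slide with a trained network, segments and
grades tumors, and writes per-slide artifacts (grade map, per-tumor CSV,
slide summary CSV, composition stacked-bar data) plus a JSON run manifest
recording the configuration hash, seed and per-stage timing — enough to
reproduce the run.  Failures on individual slides are recorded and the run
continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as lio
from .analysis import segment_tumors, slide_summary, tumor_table
from .net import GraderNetwork, grade_slide
from .stain import normalize_to_reference
from .types import REFERENCE_MPP

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline constant surfaces here with its standard default:
    224-px patches, 0.5022 µm/px, the 10% overall-grade rule, the
    2000 µm² / 50-cell IHC exclusion filters, and p < 0.01 significance."""

    model_path: str = ""
    output_dir: str = "lunggrade_out"
    seed: int = 0
    tile: int = 224
    stride: int = 112
    smooth_window: int = 5
    microns_per_pixel: float = REFERENCE_MPP
    overall_grade_threshold: float = 0.10
    connectivity: int = 8
    min_tumor_pixels: int = 1
    normalize_stain: bool = False
    ihc_min_area_um2: float = 2000.0
    ihc_min_cells: int = 50
    ihc_alpha: float = 0.01
    positivity_threshold: float = 0.05
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.overall_grade_threshold <= 0.25):
            raise ValueError("overall-grade threshold must be in (0, 0.25]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.stride > self.tile or self.stride < 1:
            raise ValueError("stride must be in [1, tile]")
        if not (0 < self.ihc_alpha < 1) or not (0 <= self.positivity_threshold <= 1):
            raise ValueError("invalid IHC thresholds")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def composition_bar_data(tumors) -> pd.DataFrame:
    """Stacked-bar data: one row per tumor, per-grade fractions, ordered by
    overall grade then area (the per-tumor composition display)."""
    df = tumor_table(tumors)
    if df.empty:
        return df
    return df.sort_values(["overall_grade", "area_um2"], ascending=[True, False]).reset_index(
        drop=True
    )


def run_pipeline(slide_paths: list[str | Path], config: PipelineConfig) -> dict:
    """Grade, segment and summarize each slide; returns the run manifest."""
    net = GraderNetwork.load(config.model_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "slides": [],
    }
    for path in slide_paths:
        path = Path(path)
        record: dict = {"slide": str(path)}
        t0 = time.perf_counter()
        try:
            image = lio.read_rgb(path)
            timings = {"read": time.perf_counter() - t0}
            if config.normalize_stain:
                t = time.perf_counter()
                image = normalize_to_reference(image)
                lio.write_rgb(out_dir / f"{path.stem}_normalized.png", image)
                record["normalized_image"] = str(out_dir / f"{path.stem}_normalized.png")
                timings["stain_norm"] = time.perf_counter() - t

            t = time.perf_counter()
            grade_map = grade_slide(
                net,
                image,
                stride=config.stride,
                smooth_window=config.smooth_window,
                tile=config.tile,
                microns_per_pixel=config.microns_per_pixel,
            )
            timings["grading"] = time.perf_counter() - t

            t = time.perf_counter()
            tumors = segment_tumors(
                grade_map,
                connectivity=config.connectivity,
                min_pixels=config.min_tumor_pixels,
                overall_grade_threshold=config.overall_grade_threshold,
            )
            summary = slide_summary(grade_map, tumors)
            timings["analysis"] = time.perf_counter() - t

            map_path = out_dir / f"{path.stem}_grademap.png"
            lio.write_grade_map(map_path, grade_map, model_version=__version__)
            tumor_csv = out_dir / f"{path.stem}_tumors.csv"
            tumor_table(tumors).to_csv(tumor_csv, index=False)
            comp_csv = out_dir / f"{path.stem}_composition.csv"
            composition_bar_data(tumors).to_csv(comp_csv, index=False)
            summary_csv = out_dir / f"{path.stem}_summary.csv"
            pd.DataFrame(
                [
                    {
                        "tumor_count": summary.tumor_count_total,
                        **{f"count_g{g}": summary.tumor_count_by_grade[g] for g in range(1, 5)},
                        "lung_area_um2": summary.lung_area_um2,
                        "tumor_area_um2": summary.tumor_area_um2,
                        "burden_fraction": summary.burden_fraction,
                        "mean_sdi": summary.mean_sdi,
                    }
                ]
            ).to_csv(summary_csv, index=False)
            record.update(
                status="ok",
                grade_map=str(map_path),
                tumor_table=str(tumor_csv),
                composition=str(comp_csv),
                summary=str(summary_csv),
                timings_s={k: round(v, 3) for k, v in timings.items()},
            )
            log.info("slide %s: %d tumors, burden %.3f", path.name, len(tumors), summary.burden_fraction)
        except Exception as exc:  # recorded failure; run continues
            log.exception("slide %s failed", path)
            record.update(status="failed", error=f"{type(exc).__name__}: {exc}")
        manifest["slides"].append(record)
    manifest["n_failed"] = sum(1 for s in manifest["slides"] if s["status"] != "ok")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
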