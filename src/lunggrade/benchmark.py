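"""Desk-scale synthetic benchmark of the full grading pipeline.

Builds a cohort of synthetic slides, constructs a slide-disjoint
area-balanced patch library, trains the desk-preset network from scratch
and reports held-out pixel accuracy.  The textures are engineered to be
separable, so this benchmarks the pipeline wiring (tiling, splits,
balancing, optimization, inference) rather than representational capacity.

Default problem sizes are chosen so the whole run takes a few minutes on a
single CPU: 12 slides of 416x416 px, 64-px tiles at stride 48, a
base-width-16 encoder, 18 epochs of Adam at 3e-3 on 8-patch minibatches.
"""

from __future__ import annotations

import time

import numpy as np
from skimage import transform as sktransform

from .analysis import segment_tumors
from .ihc import filter_tumors_for_ihc, project_cells, register_global, staining_g_test
from .net import GraderNetwork, NetworkSpec, TrainingConfig, evaluate_split
from .net.train import train
from .patches import LabelMask, balance_by_area, build_library
from .synthetic import (
    IHCPatternSpec,
    SlideLayoutSpec,
    TumorBlobSpec,
    make_ihc_pattern,
    make_synthetic_slide,
    random_slide_spec,
)
from .types import GradeMap


def build_benchmark_slides(
    seed: int,
    n_slides: int = 12,
    canvas: int = 416,
    n_tumors: int = 6,
    tumor_radius: tuple[int, int] = (40, 60),
) -> list[tuple]:
    return [
        make_synthetic_slide(
            random_slide_spec(
                seed + i, canvas_size=(canvas, canvas), n_tumors=n_tumors, tumor_radius=tumor_radius
            )
        )
        for i in range(n_slides)
    ]


def desk_benchmark(
    seed: int = 0,
    n_slides: int = 12,
    canvas: int = 416,
    quota_per_class: int = 60,
    tile: int = 64,
    stride: int = 48,
    base_width: int = 16,
    epochs: int = 18,
    minibatch: int = 8,
    lr: float = 3e-3,
) -> dict:
    """Train the desk network on synthetic textures; return metrics.

    Returns a dict with the trained network, the library, the training
    history and train/validation/test pixel accuracies plus wall time.
    """
    slides = [(rgb, LabelMask(labels)) for rgb, labels in build_benchmark_slides(seed, n_slides, canvas)]
    t0 = time.perf_counter()
    library = build_library(slides, quota_per_class=quota_per_class, size=tile, stride=stride, seed=seed)
    library = balance_by_area(library, seed=seed, max_copies_per_split=150)
    net = GraderNetwork(NetworkSpec(encoder_depth=2, base_width=base_width, seed=seed))
    cfg = TrainingConfig(epochs=epochs, minibatch=minibatch, initial_lr=lr, seed=seed)
    net, history = train(net, library, cfg)
    elapsed = time.perf_counter() - t0
    return {
        "net": net,
        "library": library,
        "history": history,
        "n_patches": len(library.patches),
        "best_val_pixel_accuracy": max(h["val_pixel_accuracy"] for h in history),
        "test_pixel_accuracy": evaluate_split(net, library, "test"),
        "wall_seconds": elapsed,
    }


def slide_recovery_accuracy(net: GraderNetwork, seed: int = 999, canvas: int = 320) -> float:
    """Grade a fresh synthetic slide and score pixel agreement with its
    ground-truth mask over tissue (the end-to-end pipeline recovery check)."""
    from .net import grade_slide

    rgb, labels = make_synthetic_slide(
        random_slide_spec(seed, canvas_size=(canvas, canvas), n_tumors=4, tumor_radius=(40, 60))
    )
    gm = grade_slide(net, rgb, stride=32, tile=64, smooth_window=5)
    tissue = labels != 0
    return float((gm.labels[tissue] == labels[tissue]).mean())


def registration_recovery(seed: int = 0, canvas: int = 256) -> dict:
    """Plant a known rigid(+slight affine) transform between a synthetic
    H&E slide and a warped copy, re-estimate it, and report the rotation
    error (degrees) and the mean mapped-point error (pixels) over tissue."""
    rng = np.random.default_rng(seed)
    he, labels = make_synthetic_slide(
        random_slide_spec(seed, canvas_size=(canvas, canvas), n_tumors=3, tumor_radius=(25, 40))
    )
    angle = float(rng.uniform(-8, 8))
    trans = rng.uniform(-12, 12, size=2)  # (x, y)
    c = (canvas - 1) / 2.0
    true_tform = (
        sktransform.AffineTransform(translation=(-c, -c))
        + sktransform.AffineTransform(rotation=np.deg2rad(angle))
        + sktransform.AffineTransform(translation=(c + trans[0], c + trans[1]))
    )
    # moving(x) = he(T(x)): the planted map takes moving-frame coords to H&E.
    moving = sktransform.warp(
        he.astype(float), true_tform, preserve_range=True, cval=255.0
    ).astype(np.uint8)
    reg = register_global(moving, he)
    rot_err = abs(((reg.rotation_deg - angle) + 180) % 360 - 180)
    rows, cols = np.nonzero(labels != 0)
    take = rng.choice(len(rows), size=min(200, len(rows)), replace=False)
    pts_he = np.column_stack([rows[take], cols[take]]).astype(float)
    # true inverse: H&E point -> moving frame, then map back with estimate
    inv = true_tform.inverse
    xy = np.column_stack([pts_he[:, 1], pts_he[:, 0]])
    pts_moving_xy = inv(xy)
    pts_moving = np.column_stack([pts_moving_xy[:, 1], pts_moving_xy[:, 0]])
    mapped = reg.map_points(pts_moving)
    err = np.linalg.norm(mapped - pts_he, axis=1)
    return {"rotation_error_deg": rot_err, "mean_point_error_px": float(err.mean())}


def enrichment_layout(seed: int, canvas: int = 360) -> SlideLayoutSpec:
    rng = np.random.default_rng(seed)
    lc = (canvas // 2, canvas // 2)
    lr = (int(canvas * 0.47), int(canvas * 0.47))
    blobs = []
    centers = [(canvas // 2 - 80, canvas // 2 - 60), (canvas // 2 + 70, canvas // 2 + 60)]
    for (cr, cc), low in zip(centers, (1, 2)):
        f = float(rng.uniform(0.4, 0.6))
        blobs.append(TumorBlobSpec(center=(cr, cc), radius=58, composition={low: f, 4: 1 - f}))
    return SlideLayoutSpec(
        canvas_size=(canvas, canvas), lung_center=lc, lung_radii=lr, tumor_blobs=blobs, seed=seed
    )


def enrichment_detection(
    seed: int = 0,
    n_seeds: int = 20,
    enrichment_g4: float = 3.0,
    baseline: float = 0.15,
    cell_density: float = 6000.0,
    min_cells: int = 200,
    alpha: float = 0.01,
) -> dict:
    """Simulate cohorts with DAB positivity enriched in Grade 4 regions and
    report how often the G-test flags mixed-grade tumors (ground-truth cell
    lists, identity registration; maps at 2 µm/px)."""
    from .ihc import RegistrationResult

    identity = RegistrationResult(
        rotation_deg=0.0,
        translation=(0.0, 0.0),
        affine=np.hstack([np.eye(2), np.zeros((2, 1))]),
        matrix=np.eye(3),
        residual=0.0,
    )
    tested = flagged = 0
    lr_g4 = []
    for k in range(n_seeds):
        s = seed * 10_000 + k
        _, labels = make_synthetic_slide(enrichment_layout(s))
        gm = GradeMap(labels, microns_per_pixel=2.0)
        tumors = segment_tumors(gm)
        _, cells = make_ihc_pattern(
            gm,
            IHCPatternSpec(
                cell_density=cell_density,
                baseline_positive_fraction=baseline,
                enrichment={4: enrichment_g4},
                nucleus_radius=2,
                seed=s,
            ),
        )
        cells, _ = project_cells(cells, identity, gm, tumors)
        eligible = filter_tumors_for_ihc(tumors, cells, min_cells=min_cells)
        for t in eligible:
            st = staining_g_test(t, cells)
            if st.testable:
                tested += 1
                if st.significant(alpha):
                    flagged += 1
                if 4 in st.likelihood_ratio:
                    lr_g4.append(st.likelihood_ratio[4])
    return {
        "tumors_tested": tested,
        "tumors_flagged": flagged,
        "detection_rate": flagged / tested if tested else float("nan"),
        "mean_lr_g4": float(np.mean(lr_g4)) if lr_g4 else float("nan"),
    }
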