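"""IHC serial-section integration: registration, cell calling, G-test.

An IHC-stained serial section (DAB chromogen + hematoxylin counterstain) is
co-registered to the adjacent H&E section in three stages — rigid (rotation
+ translation), a lightly-applied affine refinement, and per-tumor local
translation — then DAB-positive/negative cells are detected by H-DAB color
deconvolution and projected onto the H&E grade map.  Within each tumor the
spatial distribution of positive cells across grade regions is tested
against the grade-area fractions with a likelihood-ratio G-test,
``G = 2 sum O_i ln(O_i / E_i)``, where ``O_i`` is the observed positive
count in the grade-i region and ``E_i`` the total positives times the
grade-i area fraction, compared to a chi-squared distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import feature, transform
from skimage.registration import phase_cross_correlation

from .stain import HDAB_STAIN_MATRIX, rgb_to_od
from .types import ClassLabel, GradeMap, TumorObject


class RegistrationFailure(RuntimeError):
    """Raised when an image pair carries no usable registration signal."""


@dataclass
class RegistrationResult:
    """Composed IHC -> H&E mapping: rigid, affine refinement, local offsets.

    ``matrix`` is the 3x3 homogeneous transform taking IHC (x, y) = (col,
    row) coordinates to H&E coordinates (affine applied after rigid).
    ``local_offsets`` maps tumor_id to an extra (row, col) translation
    applied to points landing in that tumor's neighborhood.
    """

    rotation_deg: float
    translation: tuple[float, float]  # (row, col) in the H&E frame
    affine: np.ndarray  # 2x3 refinement applied after the rigid stage
    matrix: np.ndarray  # 3x3 composed rigid+affine
    residual: float
    local_offsets: dict[int, tuple[float, float]] = field(default_factory=dict)
    local_radius: float = 50.0

    def map_points(self, points_rc: np.ndarray) -> np.ndarray:
        """Map (row, col) points from the IHC frame to the H&E frame."""
        pts = np.asarray(points_rc, dtype=float)
        xy = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        out = xy @ self.matrix.T
        return np.column_stack([out[:, 1], out[:, 0]])


def _signal(image: np.ndarray) -> np.ndarray:
    """Smoothed tissue-on-dark grayscale in [0, 1].

    White background maps to 0; a light blur turns stain-specific detail
    (nuclear point patterns vs. H&E texture) into comparable tissue-density
    maps, which is what makes H&E/IHC pairs registrable.
    """
    g = np.asarray(image, dtype=float)
    if g.ndim == 3:
        g = g.mean(axis=2)
    return ndimage.gaussian_filter(1.0 - g / max(g.max(), 1.0), 2.0)


def _rigid_matrix(rotation_deg: float, translation_rc: tuple[float, float], shape) -> np.ndarray:
    """3x3 (x, y) matrix: rotate about the image center, then translate."""
    h, w = shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    pre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    post = np.array(
        [[1, 0, cx + translation_rc[1]], [0, 1, cy + translation_rc[0]], [0, 0, 1]], dtype=float
    )
    return post @ rot @ pre


def _warp_to(moving: np.ndarray, matrix: np.ndarray, shape) -> np.ndarray:
    tform = transform.AffineTransform(matrix=matrix)
    return transform.warp(
        moving, tform.inverse, output_shape=shape[:2], preserve_range=True, order=1
    )


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def register_global(
    ihc: np.ndarray,
    he: np.ndarray,
    downsample: int = 8,
    rotation_range_deg: float = 15.0,
    coarse_step_deg: float = 1.0,
    fine_step_deg: float = 0.1,
    affine_iters: int = 20,
) -> RegistrationResult:
    """Rigid then lightly-affine registration of an IHC slide to H&E.

    The rigid stage is a multi-resolution correlation search: a rotation
    grid (±``rotation_range_deg``) with per-angle phase-correlation
    translation on ``downsample``-times-reduced grayscale images, refined
    to ``fine_step_deg``, with a final full-resolution subpixel translation
    polish.  The affine stage perturbs the rigid solution by a small
    matrix fitted with a gradient-based optimizer capped at
    ``affine_iters`` iterations, to avoid undesired deformation.
    """
    sig_i, sig_h = _signal(ihc), _signal(he)
    if sig_i.std() < 1e-6 or sig_h.std() < 1e-6:
        raise RegistrationFailure("featureless image: no registration signal")

    scale = 1.0 / downsample
    small_i = transform.rescale(sig_i, scale, anti_aliasing=True)
    small_h = transform.rescale(sig_h, scale, anti_aliasing=True)

    def best_shift(angle: float) -> tuple[float, tuple[float, float]]:
        mat = _rigid_matrix(angle, (0.0, 0.0), small_i.shape)
        rotated = _warp_to(small_i, mat, small_h.shape)
        shift, *_ = phase_cross_correlation(
            small_h, rotated, upsample_factor=20, normalization=None
        )
        # Score candidate translations explicitly; keeps us independent of
        # shift-sign conventions.
        best = (np.inf, (0.0, 0.0))
        for s in (shift, -shift):
            m = _rigid_matrix(angle, (float(s[0]), float(s[1])), small_i.shape)
            err = _mse(_warp_to(small_i, m, small_h.shape), small_h)
            if err < best[0]:
                best = (err, (float(s[0]), float(s[1])))
        return best

    angles = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, coarse_step_deg)
    scored = [(best_shift(a), a) for a in angles]
    (err0, _), a0 = min(scored, key=lambda t: t[0][0])
    fine = np.arange(a0 - coarse_step_deg, a0 + coarse_step_deg + 1e-9, fine_step_deg)
    scored = [(best_shift(a), a) for a in fine]
    (_, shift_small), angle = min(scored, key=lambda t: t[0][0])

    # Full-resolution translation polish at the chosen angle.
    rot_full = _warp_to(sig_i, _rigid_matrix(angle, (0.0, 0.0), sig_i.shape), sig_h.shape)
    shift_full, *_ = phase_cross_correlation(
        sig_h, rot_full, upsample_factor=10, normalization=None
    )
    candidates = [tuple(np.asarray(shift_small) * downsample)]
    candidates += [tuple(shift_full), tuple(-np.asarray(shift_full))]
    best_t, best_err = None, np.inf
    for t in candidates:
        m = _rigid_matrix(angle, t, sig_i.shape)
        err = _mse(
            transform.rescale(_warp_to(sig_i, m, sig_h.shape), scale, anti_aliasing=True), small_h
        )
        if err < best_err:
            best_t, best_err = (float(t[0]), float(t[1])), err
    rigid = _rigid_matrix(angle, best_t, sig_i.shape)

    # Light affine refinement on the downsampled pair.  The translation
    # parameters live at the reduced scale; the linear part is scale-free.
    def compose(params: np.ndarray, sc: float = 1.0) -> np.ndarray:
        a, b, tx, c, d, ty = params
        aff = np.array([[1 + a, b, tx / sc], [c, 1 + d, ty / sc], [0, 0, 1]])
        return aff @ rigid

    def cost(params: np.ndarray) -> float:
        m = compose(params, sc=scale)
        return _mse(
            transform.rescale(_warp_to(sig_i, m, sig_h.shape), scale, anti_aliasing=True), small_h
        )

    res = optimize.minimize(
        cost,
        np.zeros(6),
        method="L-BFGS-B",
        bounds=[(-0.05, 0.05), (-0.05, 0.05), (-5, 5)] * 2,
        options={"maxiter": affine_iters, "eps": 1e-3},
    )
    params = res.x if cost(res.x) <= cost(np.zeros(6)) else np.zeros(6)
    matrix = compose(params, sc=scale)
    if np.linalg.det(matrix[:2, :2]) <= 0:  # no reflections
        params = np.zeros(6)
        matrix = rigid
    residual = _mse(_warp_to(sig_i, matrix, sig_h.shape), sig_h)
    return RegistrationResult(
        rotation_deg=float(angle),
        translation=best_t,
        affine=compose(params, sc=scale)[:2, :] @ np.linalg.inv(rigid),
        matrix=matrix,
        residual=residual,
    )


def register_local(
    result: RegistrationResult,
    ihc: np.ndarray,
    he: np.ndarray,
    tumors: list[TumorObject],
    radius: int = 50,
) -> RegistrationResult:
    """Per-tumor translation refinement by windowed cross-correlation.

    For each tumor, the H&E signal and the globally-warped IHC signal are
    compared over the tumor's bounding box expanded by ``radius`` pixels;
    the residual translation is the phase-correlation shift.  Shifts beyond
    the radius (or from flat/out-of-bounds windows) are rejected and the
    global solution kept (offset 0).
    """
    sig_h = _signal(he)
    warped = _warp_to(_signal(ihc), result.matrix, sig_h.shape)
    offsets: dict[int, tuple[float, float]] = {}
    H, W = sig_h.shape
    for t in tumors:
        r0, c0, r1, c1 = t.bbox
        wr0, wc0 = max(r0 - radius, 0), max(c0 - radius, 0)
        wr1, wc1 = min(r1 + radius, H - 1), min(c1 + radius, W - 1)
        if wr1 <= wr0 or wc1 <= wc0:
            continue  # region (effectively) outside bounds
        a = sig_h[wr0 : wr1 + 1, wc0 : wc1 + 1]
        b = warped[wr0 : wr1 + 1, wc0 : wc1 + 1]
        if a.std() < 1e-6 or b.std() < 1e-6:
            offsets[t.tumor_id] = (0.0, 0.0)
            continue
        # shift s: features at warped position y match H&E position y + s,
        # so s is exactly the correction added to globally-mapped points.
        shift, *_ = phase_cross_correlation(a, b, upsample_factor=10, normalization=None)
        if abs(shift[0]) > radius or abs(shift[1]) > radius:
            offsets[t.tumor_id] = (0.0, 0.0)
        else:
            offsets[t.tumor_id] = (float(shift[0]), float(shift[1]))
    result.local_offsets = offsets
    result.local_radius = float(radius)
    return result


@dataclass
class CellRecord:
    """One detected cell: IHC-frame centroid, DAB call, projected position."""

    centroid_ihc: tuple[float, float]  # (row, col)
    positive: bool
    centroid_he: tuple[float, float] | None = None
    assigned_class: ClassLabel | None = None
    tumor_id: int | None = None


def deconvolve_hdab(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an H-DAB image into (hematoxylin, DAB) concentration maps
    (base-10 OD scale, least-squares unmixing, clipped at 0)."""
    od = rgb_to_od(image).od
    conc, *_ = np.linalg.lstsq(HDAB_STAIN_MATRIX, od.reshape(-1, 3).T, rcond=None)
    h, w, _ = od.shape
    conc = np.maximum(conc, 0.0)
    return conc[0].reshape(h, w), conc[1].reshape(h, w)


def detect_cells(
    ihc: np.ndarray,
    min_distance: int = 5,
    peak_od_threshold: float = 0.1,
    dab_threshold: float = 0.2,
    dab_radius: int = 3,
    smooth_sigma: float = 1.5,
) -> list[CellRecord]:
    """Detect nuclei and call DAB positivity on an H-DAB stained image.

    Nuclei are local maxima of the smoothed hematoxylin + DAB OD with a
    minimum separation; a cell is positive iff the mean DAB OD within a
    ``dab_radius``-pixel disk around its centroid exceeds
    ``dab_threshold``.
    """
    if np.asarray(ihc).ndim != 3 or ihc.shape[2] != 3:
        raise ValueError("expected an RGB H-DAB image")
    h_conc, dab_conc = deconvolve_hdab(ihc)
    total = ndimage.gaussian_filter(h_conc + dab_conc, smooth_sigma)
    peaks = feature.peak_local_max(
        total, min_distance=min_distance, threshold_abs=peak_od_threshold, exclude_border=False
    )
    rr, cc = np.mgrid[-dab_radius : dab_radius + 1, -dab_radius : dab_radius + 1]
    disk = (rr**2 + cc**2) <= dab_radius**2
    H, W = dab_conc.shape
    cells = []
    for r, c in peaks:
        r0, r1 = max(r - dab_radius, 0), min(r + dab_radius + 1, H)
        c0, c1 = max(c - dab_radius, 0), min(c + dab_radius + 1, W)
        sub = dab_conc[r0:r1, c0:c1]
        dsub = disk[
            r0 - (r - dab_radius) : disk.shape[0] - ((r + dab_radius + 1) - r1),
            c0 - (c - dab_radius) : disk.shape[1] - ((c + dab_radius + 1) - c1),
        ]
        mean_dab = float(sub[dsub].mean()) if dsub.any() else 0.0
        cells.append(CellRecord(centroid_ihc=(float(r), float(c)), positive=mean_dab > dab_threshold))
    return cells


def tumor_id_raster(grade_map: GradeMap, tumors: list[TumorObject]) -> np.ndarray:
    out = np.zeros(grade_map.shape, dtype=np.int32)
    for t in tumors:
        out[t.pixel_mask] = t.tumor_id
    return out


def project_cells(
    cells: list[CellRecord],
    registration: RegistrationResult,
    grade_map: GradeMap,
    tumors: list[TumorObject],
) -> tuple[list[CellRecord], int]:
    """Map cells into the H&E frame and annotate class and tumor membership.

    Returns the in-bounds cells (completed records) and the count of cells
    dropped for landing outside the grade map.
    """
    if not cells:
        return [], 0
    pts = np.array([c.centroid_ihc for c in cells], dtype=float)
    mapped = registration.map_points(pts)
    # Apply per-tumor local corrections to points landing in a tumor's
    # padded bounding box (first matching tumor wins).
    if registration.local_offsets:
        boxes = {t.tumor_id: t.bbox for t in tumors}
        pad = registration.local_radius
        for i, (r, c) in enumerate(mapped):
            for tid, (dr, dc) in registration.local_offsets.items():
                r0, c0, r1, c1 = boxes[tid]
                if r0 - pad <= r <= r1 + pad and c0 - pad <= c <= c1 + pad:
                    mapped[i] = (r + dr, c + dc)
                    break
    tid_raster = tumor_id_raster(grade_map, tumors)
    H, W = grade_map.shape
    completed, dropped = [], 0
    for cell, (r, c) in zip(cells, mapped):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < H and 0 <= ci < W):
            dropped += 1
            continue
        cell.centroid_he = (float(r), float(c))
        cell.assigned_class = ClassLabel(int(grade_map.labels[ri, ci]))
        tid = int(tid_raster[ri, ci])
        cell.tumor_id = tid if tid > 0 else None
        completed.append(cell)
    return completed, dropped


def filter_tumors_for_ihc(
    tumors: list[TumorObject],
    cells: list[CellRecord],
    min_area_um2: float = 2000.0,
    min_cells: int = 50,
) -> list[TumorObject]:
    """Exclude tumors below 2000 µm² or with fewer than 50 assigned cells,
    minimizing artifacts from imperfect registration and cell calling."""
    counts: dict[int, int] = {}
    for c in cells:
        if c.tumor_id is not None:
            counts[c.tumor_id] = counts.get(c.tumor_id, 0) + 1
    return [
        t
        for t in tumors
        if t.area_um2 >= min_area_um2 and counts.get(t.tumor_id, 0) >= min_cells
    ]


@dataclass
class StainedTumorStats:
    """Per-tumor staining-enrichment record for the G-test."""

    tumor_id: int
    total_cells: int
    total_positive: int
    observed: dict[int, int]  # grade -> positive-cell count
    expected: dict[int, float]  # grade -> expected positives (area-weighted)
    G: float
    df: int
    p: float | None
    likelihood_ratio: dict[int, float]  # grade -> O_i / E_i
    testable: bool

    def significant(self, alpha: float = 0.01) -> bool:
        return self.testable and self.p is not None and self.p < alpha


def staining_g_test(tumor: TumorObject, cells: list[CellRecord]) -> StainedTumorStats:
    """Likelihood-ratio G-test for uneven positive-cell distribution.

    Expected counts per grade are the tumor's total positives times the
    grade's area fraction among graded pixels; ``G = 2 sum O ln(O/E)`` over
    grades with positive expectation (0 ln 0 := 0), with ``df`` = grades
    present − 1 and the p-value from the chi-squared upper tail.  Tumors
    with no positives or a single grade are reported as not testable.
    """
    in_tumor = [c for c in cells if c.tumor_id == tumor.tumor_id]
    positives = [c for c in in_tumor if c.positive]
    observed = {g: 0 for g in tumor.composition}
    for c in positives:
        if c.assigned_class is not None and c.assigned_class.is_grade:
            g = c.assigned_class.grade_number
            if g in observed:
                observed[g] += 1
    total_pos = sum(observed.values())
    expected = {g: total_pos * frac for g, frac in tumor.composition.items()}
    lr = {g: (observed[g] / expected[g]) if expected[g] > 0 else float("nan") for g in observed}
    df = len([g for g in expected if expected[g] > 0]) - 1
    if total_pos == 0 or df < 1:
        return StainedTumorStats(
            tumor.tumor_id, len(in_tumor), total_pos, observed, expected,
            0.0, max(df, 0), None, lr, testable=False,
        )
    G = 0.0
    for g, o in observed.items():
        if o > 0 and expected[g] > 0:
            G += o * np.log(o / expected[g])
    G *= 2.0
    p = float(stats.chi2.sf(G, df))
    return StainedTumorStats(
        tumor.tumor_id, len(in_tumor), total_pos, observed, expected,
        float(G), df, p, lr, testable=True,
    )


def positivity_by_grade(
    slides: list[list[tuple[TumorObject, StainedTumorStats]]],
    positivity_threshold: float = 0.05,
    alpha: float = 0.01,
):
    """Fraction of positively stained tumors per overall grade, mean ± SD
    across slides, plus the per-grade likelihood ratios of tumors with a
    significant G-test.

    A tumor counts as positively stained iff its positive-cell fraction is
    at least ``positivity_threshold``.
    """
    import pandas as pd

    if slides and isinstance(slides[0], tuple):  # single flat slide given
        slides = [slides]  # type: ignore[list-item]
    per_slide = []
    enrich_rows = []
    for si, slide in enumerate(slides):
        fractions: dict[int, list[bool]] = {}
        for tumor, st in slide:
            pos = st.total_positive / st.total_cells if st.total_cells else 0.0
            fractions.setdefault(tumor.overall_grade, []).append(pos >= positivity_threshold)
            if st.significant(alpha):
                for g, r in st.likelihood_ratio.items():
                    enrich_rows.append(
                        {
                            "slide": si,
                            "tumor_id": tumor.tumor_id,
                            "overall_grade": tumor.overall_grade,
                            "grade_region": g,
                            "likelihood_ratio": r,
                            "log_likelihood_ratio": float(np.log(r)) if r > 0 else float("-inf"),
                        }
                    )
        per_slide.append(
            {g: float(np.mean(v)) for g, v in fractions.items() if v}
        )
    rows = []
    for g in (1, 2, 3, 4):
        vals = [d[g] for d in per_slide if g in d]
        rows.append(
            {
                "overall_grade": g,
                "fraction_positive_mean": float(np.mean(vals)) if vals else None,
                "fraction_positive_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                "n_slides": len(vals),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(enrich_rows)
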