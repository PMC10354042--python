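"""Rater-agreement and detection metrics.

Tumor-level agreement between an automated grade map and a human rater is
summarized by a confusion matrix over ordered grade categories and by
Cohen's kappa, plain and linear-weighted.  Pixel-level agreement is
summarized by area-based precision/recall/F1 per class and micro-averaged,
and by predicted-to-manual area ratios.  Effect sizes follow the pooled-SD
Cohen's d and the rank-test standardized r = z / (n1 + n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import assign_overall_grade
from .types import ClassLabel, GradeMap


@dataclass
class ConfusionMatrix:
    """Rater-vs-rater count table with ordered row/column category labels."""

    categories_rows: list[str]
    categories_cols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.categories_rows), len(self.categories_cols)):
            raise ValueError("counts shape must match category lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.categories_rows, columns=self.categories_cols)


@dataclass
class AgreementStats:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    se_kappa: float
    ci95: tuple[float, float]
    weighting: str = "none"


def _embed_square(cm: ConfusionMatrix) -> tuple[list[str], np.ndarray]:
    """Embed both raters' category sets in one ordered list (zero marginals
    for categories a rater never used)."""
    common = list(cm.categories_rows)
    for c in cm.categories_cols:
        if c not in common:
            common.append(c)
    k = len(common)
    sq = np.zeros((k, k), dtype=np.int64)
    for i, r in enumerate(cm.categories_rows):
        for j, c in enumerate(cm.categories_cols):
            sq[common.index(r), common.index(c)] = cm.counts[i, j]
    return common, sq


def cohens_kappa(cm: ConfusionMatrix, weighting: str = "none") -> AgreementStats:
    """Cohen's kappa with optional linear weights over ordered categories.

    Linear weights credit near-miss calls: ``w_ij = 1 - |i - j| / (k - 1)``
    over the common ordered category list.  The standard error is the
    large-sample (Fleiss-Cohen-Everitt) estimate with a normal 95% CI; the
    identity-weight case reduces to the usual unweighted kappa SE.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    _, sq = _embed_square(cm)
    k = sq.shape[0]
    n = sq.sum()
    p = sq / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)

    if weighting == "none":
        w = np.eye(k)
    elif weighting == "linear":
        idx = np.arange(k)
        w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-12:
        return AgreementStats(p_o, p_e, float("nan"), float("nan"), (float("nan"),) * 2, weighting)
    kappa = (p_o - p_e) / (1.0 - p_e)

    w_row = w @ col  # E[w | rater A category i]
    w_col = row @ w  # E[w | rater B category j]
    term = w * (1.0 - p_e) - (w_row[:, None] + w_col[None, :]) * (1.0 - p_o)
    var = ((p * term**2).sum() - (p_o * p_e - 2.0 * p_e + p_o) ** 2) / (n * (1.0 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return AgreementStats(p_o, p_e, float(kappa), se, ci, weighting)


@dataclass
class TumorMatch:
    """Detection/grading record for one manually annotated tumor."""

    manual_grade: int
    detected: bool
    call: str  # "Grade 1".."Grade 4" or the modal normal-class name


GRADE_NAMES = {1: "Grade 1", 2: "Grade 2", 3: "Grade 3", 4: "Grade 4"}
NORMAL_NAMES = {
    ClassLabel.NORMAL_ALVEOLI: "normal alveoli",
    ClassLabel.NORMAL_AIRWAY: "normal airway",
    ClassLabel.BACKGROUND: "background",
}


def match_tumors(
    manual_regions: list[tuple[np.ndarray, int]],
    grade_map: GradeMap,
    threshold: float = 0.10,
) -> list[TumorMatch]:
    """Score each manually segmented tumor against the grade map.

    A manual tumor is *detected* iff at least one pixel inside its region
    carries a tumor grade; its automated overall grade is then assigned by
    the highest-grade-at-least-``threshold`` rule over the in-region grade
    composition.  Undetected tumors are recorded with the modal normal
    class inside the region.

    Parameters
    ----------
    manual_regions : list of (mask, grade)
        Boolean region rasters in the grade-map frame with the manual grade.
    """
    out = []
    labels = grade_map.labels
    for mask, manual_grade in manual_regions:
        inside = labels[np.asarray(mask, dtype=bool)]
        if inside.size == 0:
            raise ValueError("empty manual region")
        grade_counts = {
            g: int(np.count_nonzero(inside == int(ClassLabel.GRADE1) + g - 1))
            for g in range(1, 5)
        }
        total = sum(grade_counts.values())
        if total > 0:
            comp = {g: c / total for g, c in grade_counts.items() if c > 0}
            call = GRADE_NAMES[assign_overall_grade(comp, threshold=threshold)]
            out.append(TumorMatch(manual_grade, True, call))
        else:
            vals, counts = np.unique(inside, return_counts=True)
            modal = ClassLabel(int(vals[np.argmax(counts)]))
            out.append(TumorMatch(manual_grade, False, NORMAL_NAMES.get(modal, modal.name)))
    return out


def confusion_from_matches(matches: list[TumorMatch]) -> ConfusionMatrix:
    """Tumor-grade confusion matrix: rows automated call (Normal, Grades
    1-4), columns manual grade (1-4).  All undetected tumors pool into the
    Normal row."""
    rows = ["Normal", "Grade 1", "Grade 2", "Grade 3", "Grade 4"]
    cols = ["Grade 1", "Grade 2", "Grade 3", "Grade 4"]
    counts = np.zeros((5, 4), dtype=np.int64)
    for m in matches:
        r = rows.index(m.call) if m.call in rows else 0
        counts[r, m.manual_grade - 1] += 1
    return ConfusionMatrix(rows, cols, counts)


def per_class_f1(
    pred_area: dict, true_area: dict, overlap_area: dict
) -> dict[str, dict[str, float | None]]:
    """Area-based precision/recall/F1 per class plus a micro average.

    Metrics with a zero denominator are reported as ``None`` (missing), not
    zero; classes absent from both raters are excluded from the micro pool.
    """
    classes = sorted(set(pred_area) | set(true_area), key=str)
    out: dict[str, dict[str, float | None]] = {}
    pooled_overlap = pooled_pred = pooled_true = 0.0
    for c in classes:
        pa = float(pred_area.get(c, 0.0))
        ta = float(true_area.get(c, 0.0))
        ov = float(overlap_area.get(c, 0.0))
        if ov > min(pa, ta) + 1e-9:
            raise ValueError(f"overlap exceeds marginal area for class {c}")
        if pa == 0 and ta == 0:
            out[str(c)] = {"precision": None, "recall": None, "f1": None}
            continue
        pooled_overlap += ov
        pooled_pred += pa
        pooled_true += ta
        prec = ov / pa if pa > 0 else None
        rec = ov / ta if ta > 0 else None
        f1 = (
            2 * prec * rec / (prec + rec)
            if prec is not None and rec is not None and (prec + rec) > 0
            else None
        )
        out[str(c)] = {"precision": prec, "recall": rec, "f1": f1}
    micro_p = pooled_overlap / pooled_pred if pooled_pred > 0 else None
    micro_r = pooled_overlap / pooled_true if pooled_true > 0 else None
    micro_f = (
        2 * micro_p * micro_r / (micro_p + micro_r)
        if micro_p is not None and micro_r is not None and (micro_p + micro_r) > 0
        else None
    )
    out["micro"] = {"precision": micro_p, "recall": micro_r, "f1": micro_f}
    return out


def area_ratio(pred_area: dict, manual_area: dict) -> dict[str, float | None]:
    """Predicted / manual area per class; ``None`` where manual area is zero."""
    out: dict[str, float | None] = {}
    for c in sorted(set(pred_area) | set(manual_area), key=str):
        ma = float(manual_area.get(c, 0.0))
        out[str(c)] = float(pred_area.get(c, 0.0)) / ma if ma > 0 else None
    return out


def cohens_d(mean1: float, mean2: float, s_pooled: float) -> float:
    """Cohen's d with pooled standard deviation."""
    if s_pooled <= 0:
        raise ValueError("pooled SD must be positive")
    return (mean1 - mean2) / s_pooled


def effect_size_r(z: float, n1: int, n2: int) -> float:
    """Standardized effect size for rank tests, r = z / (n1 + n2)."""
    if n1 + n2 <= 0:
        raise ValueError("n1 + n2 must be positive")
    return z / (n1 + n2)
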