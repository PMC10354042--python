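"""IHC registration, cell detection, projection, and the staining G-test."""

import numpy as np
import pytest
from scipy import stats as sps
from skimage import transform as sktransform

from lunggrade import synthetic
from lunggrade.analysis import segment_tumors
from lunggrade.ihc import (
    CellRecord,
    RegistrationFailure,
    RegistrationResult,
    detect_cells,
    filter_tumors_for_ihc,
    positivity_by_grade,
    project_cells,
    register_global,
    register_local,
    staining_g_test,
)
from lunggrade.types import ClassLabel, GradeMap, TumorObject


def _he_image(seed=11, size=256):
    spec = synthetic.random_slide_spec(seed, canvas_size=(size, size), n_tumors=3,
                                       tumor_radius=(25, 40))
    return synthetic.make_synthetic_slide(spec)


def _identity_registration() -> RegistrationResult:
    return RegistrationResult(
        rotation_deg=0.0,
        translation=(0.0, 0.0),
        affine=np.hstack([np.eye(2), np.zeros((2, 1))]),
        matrix=np.eye(3),
        residual=0.0,
    )


class TestGlobalRegistration:
    def test_identity_on_identical_images(self):
        he, _ = _he_image()
        reg = register_global(he, he)
        assert abs(reg.rotation_deg) <= 0.1
        assert np.hypot(*reg.translation) <= 0.5

    def test_recovers_translation(self):
        he, _ = _he_image()
        moved = np.roll(np.roll(he, 10, axis=0), 5, axis=1)
        reg = register_global(moved, he)
        # mapping IHC->H&E must undo the (10, 5) roll
        assert abs(reg.translation[0] + 10) <= 1.0
        assert abs(reg.translation[1] + 5) <= 1.0
        assert abs(reg.rotation_deg) <= 0.3

    def test_recovers_rotation(self):
        he, _ = _he_image()
        rotated = (
            sktransform.rotate(he.astype(float), 5.0, preserve_range=True, cval=255)
        ).astype(np.uint8)
        reg = register_global(rotated, he)
        assert abs(reg.rotation_deg + 5.0) <= 0.5 or abs(reg.rotation_deg - 5.0) <= 0.5
        # the composed map must align the pair: check a central point
        pts = np.array([[128.0, 128.0]])
        mapped = reg.map_points(pts)
        assert np.hypot(*(mapped[0] - pts[0])) < 2.0

    def test_featureless_image_rejected(self):
        flat = np.full((128, 128, 3), 240, dtype=np.uint8)
        he, _ = _he_image()
        with pytest.raises(RegistrationFailure):
            register_global(flat, he)

    def test_no_reflection_in_affine(self):
        he, _ = _he_image()
        reg = register_global(he, he)
        assert np.linalg.det(reg.matrix[:2, :2]) > 0


class TestLocalRegistration:
    def test_local_shift_recovered(self):
        he, labels = _he_image(seed=21)
        gm = GradeMap(labels)
        tumors = segment_tumors(gm)
        assert tumors
        # shift the content of the first tumor's neighborhood by +8 px
        moved = he.copy()
        t = tumors[0]
        r0, c0, r1, c1 = t.bbox
        pad = 12
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p, c1p = min(r1 + pad, he.shape[0] - 1), min(c1 + pad, he.shape[1] - 1)
        block = he[r0p : r1p + 1, c0p : c1p + 1]
        moved[r0p : r1p + 1, c0p : c1p + 1] = 245
        dr = dc = 8
        moved[r0p + dr : r1p + 1 + dr, c0p + dc : c1p + 1 + dc] = block[
            : he.shape[0] - r0p - dr, : he.shape[1] - c0p - dc
        ]
        reg = register_local(_identity_registration(), moved, he, [t], radius=20)
        off = reg.local_offsets[t.tumor_id]
        assert abs(off[0] + dr) <= 1.5 and abs(off[1] + dc) <= 1.5

    def test_aligned_pair_offsets_near_zero(self):
        he, labels = _he_image(seed=22)
        tumors = segment_tumors(GradeMap(labels))
        reg = register_local(_identity_registration(), he, he, tumors, radius=15)
        for off in reg.local_offsets.values():
            assert abs(off[0]) <= 1 and abs(off[1]) <= 1

    def test_flat_window_keeps_global(self):
        he = np.full((128, 128, 3), 240, dtype=np.uint8)
        t = TumorObject(
            tumor_id=1, pixel_mask=np.zeros((128, 128), bool), pixel_count=10,
            area_um2=10.0, grade_pixels={2: 10}, composition={2: 1.0},
            overall_grade=2, bbox=(40, 40, 60, 60),
        )
        reg = register_local(_identity_registration(), he, he, [t], radius=15)
        assert reg.local_offsets[1] == (0.0, 0.0)


class TestDetectCells:
    def test_fixture_counts_recovered(self):
        labels = np.full((200, 200), int(ClassLabel.GRADE3), dtype=np.uint8)
        gm = GradeMap(labels, microns_per_pixel=2.0)
        spec = synthetic.IHCPatternSpec(
            cell_density=400.0, baseline_positive_fraction=0.4, nucleus_radius=3, seed=3
        )
        img, truth = synthetic.make_ihc_pattern(gm, spec)
        n_true = len(truth)
        n_pos_true = sum(c.positive for c in truth)
        cells = detect_cells(img)
        assert n_true > 20
        assert abs(len(cells) - n_true) <= max(3, 0.06 * n_true)
        assert abs(sum(c.positive for c in cells) - n_pos_true) <= max(2, 0.06 * n_pos_true)

    def test_blank_image_no_cells(self):
        blank = np.full((100, 100, 3), 255, dtype=np.uint8)
        assert detect_cells(blank) == []

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            detect_cells(np.zeros((50, 50), dtype=np.uint8))


class TestProjectCells:
    def _setup(self):
        labels = np.full((60, 60), int(ClassLabel.NORMAL_ALVEOLI), dtype=np.uint8)
        labels[10:30, 10:30] = int(ClassLabel.GRADE3)
        gm = GradeMap(labels)
        tumors = segment_tumors(gm)
        return gm, tumors

    def test_identity_projection_assigns_class_and_tumor(self):
        gm, tumors = self._setup()
        cells = [CellRecord((15.0, 15.0), True), CellRecord((50.0, 50.0), False)]
        done, dropped = project_cells(cells, _identity_registration(), gm, tumors)
        assert dropped == 0
        assert done[0].assigned_class == ClassLabel.GRADE3
        assert done[0].tumor_id == tumors[0].tumor_id
        assert done[1].assigned_class == ClassLabel.NORMAL_ALVEOLI
        assert done[1].tumor_id is None

    def test_out_of_bounds_dropped_and_counted(self):
        gm, tumors = self._setup()
        cells = [CellRecord((-5.0, 10.0), True), CellRecord((15.0, 15.0), True)]
        done, dropped = project_cells(cells, _identity_registration(), gm, tumors)
        assert dropped == 1 and len(done) == 1


def _tumor(tid, composition, area_um2=2500.0):
    return TumorObject(
        tumor_id=tid, pixel_mask=np.zeros((1, 1), bool), pixel_count=1,
        area_um2=area_um2, grade_pixels={g: 1 for g in composition},
        composition=composition, overall_grade=max(composition),
    )


def _cells_for(tid, per_grade_positive: dict, per_grade_negative: dict | None = None):
    cells = []
    for g, n in per_grade_positive.items():
        cls = ClassLabel(int(ClassLabel.GRADE1) + g - 1)
        cells += [CellRecord((0, 0), True, (0, 0), cls, tid) for _ in range(n)]
    for g, n in (per_grade_negative or {}).items():
        cls = ClassLabel(int(ClassLabel.GRADE1) + g - 1)
        cells += [CellRecord((0, 0), False, (0, 0), cls, tid) for _ in range(n)]
    return cells


class TestExclusionFilters:
    def test_area_boundary(self):
        """Tumors below 2000 µm² are excluded; exactly 2000 µm² is kept."""
        cells = _cells_for(1, {2: 60})
        small = _tumor(1, {2: 1.0}, area_um2=1999.9)
        boundary = _tumor(1, {2: 1.0}, area_um2=2000.0)
        assert filter_tumors_for_ihc([small], cells) == []
        assert filter_tumors_for_ihc([boundary], cells) == [boundary]

    def test_cell_count_boundary(self):
        """Fewer than 50 assigned cells excludes; exactly 50 is kept."""
        t = _tumor(1, {2: 1.0}, area_um2=2500.0)
        assert filter_tumors_for_ihc([t], _cells_for(1, {2: 49})) == []
        assert filter_tumors_for_ihc([t], _cells_for(1, {2: 50})) == [t]

    def test_both_conditions_required(self):
        t = _tumor(1, {2: 1.0}, area_um2=1999.9)
        assert filter_tumors_for_ihc([t], _cells_for(1, {2: 60})) == []


class TestGTest:
    def test_proportional_counts_give_zero(self):
        t = _tumor(1, {2: 0.75, 4: 0.25})
        st = staining_g_test(t, _cells_for(1, {2: 30, 4: 10}))
        assert st.G == pytest.approx(0.0, abs=1e-12)
        assert st.p == pytest.approx(1.0)

    def test_two_category_case_matches_chi2_oracle(self):
        t = _tumor(1, {3: 0.5, 4: 0.5})
        st = staining_g_test(t, _cells_for(1, {3: 30, 4: 10}))
        expected_G = 2 * (30 * np.log(30 / 20) + 10 * np.log(10 / 20))
        assert st.G == pytest.approx(expected_G, abs=1e-10)
        assert st.df == 1
        assert st.p == pytest.approx(float(sps.chi2.sf(expected_G, 1)), abs=1e-12)
        assert st.significant()

    def test_single_grade_not_testable(self):
        st = staining_g_test(_tumor(1, {3: 1.0}), _cells_for(1, {3: 40}))
        assert not st.testable

    def test_zero_positives_not_testable(self):
        st = staining_g_test(_tumor(1, {2: 0.5, 3: 0.5}), _cells_for(1, {}, {2: 30, 3: 30}))
        assert not st.testable

    def test_expected_sums_match_observed(self):
        t = _tumor(1, {1: 0.2, 3: 0.5, 4: 0.3})
        st = staining_g_test(t, _cells_for(1, {1: 5, 3: 25, 4: 30}))
        assert sum(st.expected.values()) == pytest.approx(sum(st.observed.values()))
        assert st.df == 2

    def test_matches_pearson_chi2_for_small_deviations(self):
        """G is first-order equivalent to the Pearson statistic."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            frac = rng.dirichlet([5, 5])
            total = 400
            e = total * frac
            o = np.round(e * (1 + rng.uniform(-0.08, 0.08, 2))).astype(int)
            t = _tumor(1, {1: frac[0], 2: frac[1]})
            st = staining_g_test(t, _cells_for(1, {1: int(o[0]), 2: int(o[1])}))
            e_st = np.array([st.expected[1], st.expected[2]])
            chi2 = float((((o - e_st) ** 2) / e_st).sum())
            if chi2 > 0.5:
                assert abs(st.G - chi2) / chi2 < 0.05


class TestPositivityByGrade:
    def test_all_positive_tumors(self):
        slide = []
        for tid, grade in enumerate((2, 3, 4), start=1):
            t = _tumor(tid, {grade: 1.0})
            st = staining_g_test(t, _cells_for(tid, {grade: 30}, {grade: 70}))
            slide.append((t, st))
        table, _ = positivity_by_grade([slide], positivity_threshold=0.05)
        present = table.dropna(subset=["fraction_positive_mean"])
        assert (present["fraction_positive_mean"] == 1.0).all()

    def test_fractions_in_unit_interval(self):
        rng = np.random.default_rng(1)
        slide = []
        for tid in range(1, 6):
            grade = int(rng.integers(1, 5))
            t = _tumor(tid, {grade: 1.0})
            npos = int(rng.integers(0, 20))
            st = staining_g_test(t, _cells_for(tid, {grade: npos}, {grade: 60 - npos}))
            slide.append((t, st))
        table, _ = positivity_by_grade([slide])
        vals = table["fraction_positive_mean"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_planted_enrichment_raises_g4_likelihood_ratio(self):
        """Over seeded simulations, G4-region enrichment shows up as mean
        likelihood ratio > 1 in G4 and < 1 in the other grade."""
        lr4, lr1 = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = _tumor(1, {1: 0.5, 4: 0.5})
            n = 150
            pos1 = int(rng.binomial(n, 0.10))
            pos4 = int(rng.binomial(n, 0.30))
            st = staining_g_test(
                t, _cells_for(1, {1: pos1, 4: pos4}, {1: n - pos1, 4: n - pos4})
            )
            lr4.append(st.likelihood_ratio[4])
            lr1.append(st.likelihood_ratio[1])
        assert np.mean(lr4) > 1.0 > np.mean(lr1)
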