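"""Tumor segmentation, overall grade, diversity, and slide summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lunggrade.analysis import (
    assign_overall_grade,
    grade_area_within,
    segment_tumors,
    shannon_diversity,
    size_distribution,
    slide_summary,
    tumor_table,
)
from lunggrade.types import ClassLabel, GradeMap, TumorObject

G1, G2, G3, G4 = (int(ClassLabel.GRADE1), int(ClassLabel.GRADE2),
                  int(ClassLabel.GRADE3), int(ClassLabel.GRADE4))
ALV = int(ClassLabel.NORMAL_ALVEOLI)


class TestOverallGrade:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ({2: 0.50, 3: 0.39, 4: 0.11}, 4),
            ({3: 0.91, 4: 0.09}, 3),
            ({3: 0.90, 4: 0.10}, 4),  # the 10% boundary is inclusive
            ({1: 1.0}, 1),
            ({1: 0.905, 4: 0.095}, 1),
        ],
    )
    def test_rule_examples(self, comp, expected):
        assert assign_overall_grade(comp) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            assign_overall_grade({1: 0.0, 2: 0.0})

    def test_agrees_with_brute_force_on_random_compositions(self):
        """The highest-grade-at-least-10% rule vs exhaustive search."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            p = rng.dirichlet(np.full(4, 0.5))
            comp = {g + 1: p[g] for g in range(4)}
            qualifying = [g for g in (1, 2, 3, 4) if comp[g] >= 0.10 - 1e-12]
            assert assign_overall_grade(comp) == max(qualifying)


class TestShannonDiversity:
    def test_closed_forms(self):
        assert shannon_diversity({1: 1.0}) == 0.0
        assert shannon_diversity({1: 0.5, 2: 0.5}) == pytest.approx(np.log(2))
        assert shannon_diversity({g: 0.25 for g in range(1, 5)}) == pytest.approx(np.log(4))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_permutation_invariance(self, weights):
        p = np.array(weights) / sum(weights)
        sdi = shannon_diversity(p)
        assert 0.0 <= sdi <= np.log(4) + 1e-12
        assert shannon_diversity(p[::-1]) == pytest.approx(sdi)
        if len(p) == 1:
            assert sdi == 0.0


class TestSegmentation:
    def test_two_separated_blobs(self):
        lab = np.full((20, 20), ALV, dtype=np.uint8)
        lab[2:6, 2:6] = G2
        lab[12:16, 12:16] = G2
        tumors = segment_tumors(GradeMap(lab))
        assert len(tumors) == 2
        assert [t.tumor_id for t in tumors] == [1, 2]

    def test_diagonal_touching_depends_on_connectivity(self):
        lab = np.full((12, 12), ALV, dtype=np.uint8)
        lab[2:5, 2:5] = G3
        lab[5:8, 5:8] = G4  # corners touch at (4,4)-(5,5)
        assert len(segment_tumors(GradeMap(lab), connectivity=8)) == 1
        assert len(segment_tumors(GradeMap(lab), connectivity=4)) == 2

    def test_all_normal_map(self):
        assert segment_tumors(GradeMap(np.full((8, 8), ALV, dtype=np.uint8))) == []

    def test_pixel_partition(self, small_grade_map):
        tumors = segment_tumors(small_grade_map)
        total = int(small_grade_map.grade_mask().sum())
        assert sum(t.pixel_count for t in tumors) == total
        for t in tumors:
            assert sum(t.grade_pixels.values()) == t.pixel_count
            assert sum(t.composition.values()) == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= t.sdi <= np.log(4) + 1e-12

    def test_min_pixels_floor(self):
        lab = np.full((10, 10), ALV, dtype=np.uint8)
        lab[0, 0] = G1
        lab[5:8, 5:8] = G2
        assert len(segment_tumors(GradeMap(lab), min_pixels=2)) == 1

    def test_normal_holes_excluded_from_composition(self):
        lab = np.full((10, 10), ALV, dtype=np.uint8)
        lab[2:8, 2:8] = G3
        lab[4:6, 4:6] = ALV  # hole
        (t,) = segment_tumors(GradeMap(lab))
        assert t.pixel_count == 36 - 4
        assert t.composition == {3: 1.0}


class TestSlideSummary:
    def test_burden_example(self):
        lab = np.zeros((10, 10), dtype=np.uint8)
        lab[:, :] = ALV  # 100 lung pixels
        lab[0, :10] = G3  # 10-px tumor
        gm = GradeMap(lab, microns_per_pixel=1.0)
        tumors = segment_tumors(gm)
        s = slide_summary(gm, tumors)
        assert s.burden_fraction == pytest.approx(0.10)
        assert s.lung_area_um2 == pytest.approx(100.0)

    def test_attribution_conservation(self, small_grade_map):
        tumors = segment_tumors(small_grade_map)
        s = slide_summary(small_grade_map, tumors)
        assert sum(s.tumor_area_by_overall_grade.values()) == pytest.approx(s.tumor_area_um2)
        assert sum(s.tumor_area_by_pixel_grade.values()) == pytest.approx(s.tumor_area_um2)
        assert sum(s.tumor_count_by_grade.values()) == s.tumor_count_total
        assert 0.0 <= s.burden_fraction <= 1.0

    def test_mixed_tumor_attribution(self):
        lab = np.full((12, 12), ALV, dtype=np.uint8)
        lab[2:7, 2:8] = G2  # 30 px
        lab[7:9, 2:8] = G3  # 12 px (adjacent -> one tumor), 12/42 = 28.6% -> overall G3
        gm = GradeMap(lab, microns_per_pixel=1.0)
        (t,) = segment_tumors(gm)
        assert t.overall_grade == 3
        s = slide_summary(gm, [t])
        assert s.tumor_area_by_overall_grade[3] == pytest.approx(42.0)
        assert s.tumor_area_by_overall_grade[2] == 0.0
        assert s.tumor_area_by_pixel_grade[2] == pytest.approx(30.0)
        assert s.tumor_area_by_pixel_grade[3] == pytest.approx(12.0)

    def test_zero_lung_area_rejected(self):
        with pytest.raises(ValueError):
            slide_summary(GradeMap(np.zeros((4, 4), dtype=np.uint8)), [])


def _mini_tumor(tid, grade_pixels, mpp=1.0):
    count = sum(grade_pixels.values())
    comp = {g: c / count for g, c in grade_pixels.items() if c > 0}
    return TumorObject(
        tumor_id=tid,
        pixel_mask=np.zeros((1, 1), dtype=bool),
        pixel_count=count,
        area_um2=count * mpp**2,
        grade_pixels=grade_pixels,
        composition=comp,
        overall_grade=assign_overall_grade(comp),
        sdi=shannon_diversity(comp),
    )


class TestGradeAreaWithin:
    def test_enumeration_fixture(self):
        tumors = [
            _mini_tumor(1, {2: 60, 3: 40}),  # overall G3
            _mini_tumor(2, {2: 100}),  # overall G2
            _mini_tumor(3, {3: 30, 2: 10}),  # overall G3
        ]
        # G2 pixels inside overall-G3 tumors: 60 + 10 of 170 total
        assert grade_area_within(tumors, 2, 3) == pytest.approx(70 / 170)
        assert grade_area_within(tumors, 3, 3) == pytest.approx(1.0)
        assert grade_area_within(tumors, 3, 2) == pytest.approx(0.0)
        assert grade_area_within(tumors, 4, 3) is None  # no G4 pixels anywhere


class TestSizeDistribution:
    def test_cdf_steps(self):
        tumors = [_mini_tumor(i + 1, {2: a}) for i, a in enumerate([1, 1, 2])]
        d = size_distribution(tumors)
        assert list(d.areas_um2) == [1.0, 1.0, 2.0]
        assert d.cdf[1] == pytest.approx(2 / 3)
        assert d.cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(d.cdf) >= 0)

    def test_minimal_count_for_half_area(self):
        tumors = [_mini_tumor(1, {2: 60}), _mini_tumor(2, {2: 25}), _mini_tumor(3, {2: 15})]
        assert size_distribution(tumors).min_tumors_for_half_area == 1


def test_tumor_table_columns(small_grade_map):
    tumors = segment_tumors(small_grade_map)
    df = tumor_table(tumors)
    assert {"tumor_id", "area_um2", "overall_grade", "sdi"} <= set(df.columns)
    assert len(df) == len(tumors)
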