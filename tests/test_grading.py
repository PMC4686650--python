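"""Grading-table fidelity, score arithmetic and threshold fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ihiscale import grading
from ihiscale.errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateInputError,
    IncompleteAssessmentError,
    InvalidGeometryError,
    NotApplicableError,
)
from ihiscale.grading import (
    C1Observation,
    C2Observation,
    C3Observation,
    C4Observation,
    C5Observation,
    CriterionGrades,
    HippocampusAssessment,
    classify_hippocampus,
    classify_roundness,
    classify_verticality,
    exposure_relation_from_lengths,
    grade_c1,
    grade_c2,
    grade_c3,
    grade_c4,
    grade_c5,
    ihi_score,
    optimal_threshold,
)

# Independent hard-coded oracles for the published grading tables.
C1_ORACLE = {
    ("flat", "horizontal"): 0.0, ("flat", "oblique"): 0.5,
    ("round", "horizontal"): 0.5, ("round", "oblique"): 1.0,
    ("round", "vertical"): 2.0, ("oval", "horizontal"): 1.0,
    ("oval", "oblique"): 1.5, ("oval", "vertical"): 2.0,
}
C2_ORACLE = {
    ("CS_less_H", "horizontal"): 0.0, ("CS_less_H", "oblique"): 0.5,
    ("CS_less_H", "vertical"): 0.5, ("CS_equal_H", "horizontal"): 1.0,
    ("CS_equal_H", "oblique"): 1.0, ("CS_equal_H", "vertical"): 1.5,
    ("CS_greater_H", "horizontal"): 1.0, ("CS_greater_H", "oblique"): 1.5,
    ("CS_greater_H", "vertical"): 2.0,
}
C3_ORACLE = {
    ("much_less", "emptied"): 2.0, ("much_less", "filled"): 2.0,
    ("less", "emptied"): 1.0, ("less", "filled"): 1.5,
    ("equal", "emptied"): 0.5, ("equal", "filled"): 1.0,
    ("greater", "emptied"): 0.0, ("greater", "filled"): 0.5,
    ("much_greater", "emptied"): 0.0, ("much_greater", "filled"): 0.0,
}
C5_ORACLE = {"none": 0.0, "oblique_crossing": 1.0, "vertical_crossing": 2.0}


class TestGradingTables:
    def test_c1_exhaustive(self):
        for (roundness, verticality), expected in C1_ORACLE.items():
            assert grade_c1(C1Observation(roundness, verticality)) == expected

    def test_c1_flat_vertical_not_applicable(self):
        with pytest.raises(NotApplicableError):
            grade_c1(C1Observation("flat", "vertical"))

    def test_c2_exhaustive(self):
        for (relation, verticality), expected in C2_ORACLE.items():
            assert grade_c2(C2Observation(relation, verticality)) == expected

    def test_c3_exhaustive(self):
        for (relation, th), expected in C3_ORACLE.items():
            assert grade_c3(C3Observation(relation, th)) == expected

    def test_c3_extremes_ignore_temporal_horn(self):
        for th in ("emptied", "filled"):
            assert grade_c3(C3Observation("much_less", th)) == 2.0
            assert grade_c3(C3Observation("much_greater", th)) == 0.0

    def test_c4(self):
        assert grade_c4(C4Observation(True)) == 2.0
        assert grade_c4(C4Observation(False)) == 0.0

    def test_c5_exhaustive(self):
        for crossing, expected in C5_ORACLE.items():
            assert grade_c5(C5Observation(crossing)) == expected

    def test_invalid_categories_rejected(self):
        with pytest.raises(DataValidationError):
            C1Observation("roundish", "horizontal")
        with pytest.raises(DataValidationError):
            C2Observation("CS_less_H", "diagonal")
        with pytest.raises(DataValidationError):
            C5Observation("sideways")

    def test_invisible_c3a_forces_much_less(self):
        with pytest.raises(DataValidationError):
            C3Observation("equal", "filled", c3a_visible=False)
        assert grade_c3(C3Observation("much_less", "filled", c3a_visible=False)) == 2.0


class TestGeometryAdapters:
    @pytest.mark.parametrize(
        "c1a, c1b, expected",
        [(10, 5, "flat"), (7, 7, "round"), (5, 8, "oval"), (10, 9.5, "round")],
    )
    def test_roundness(self, c1a, c1b, expected):
        assert classify_roundness(c1a, c1b, 0.1) == expected

    def test_roundness_rejects_nonpositive(self):
        with pytest.raises(InvalidGeometryError):
            classify_roundness(0, 5)
        with pytest.raises(InvalidGeometryError):
            classify_roundness(5, -1)

    @pytest.mark.parametrize(
        "angle, expected",
        [(0, "horizontal"), (10, "horizontal"), (45, "oblique"),
         (80, "vertical"), (85, "vertical")],
    )
    def test_verticality(self, angle, expected):
        assert classify_verticality(angle, 10) == expected

    def test_verticality_domain(self):
        with pytest.raises(InvalidGeometryError):
            classify_verticality(91, 10)
        with pytest.raises(ConfigurationError):
            classify_verticality(45, 50)

    @pytest.mark.parametrize(
        "c3a, c3b, expected",
        [(0, 5, "much_less"), (1, 5, "much_less"), (2, 5, "less"),
         (5, 5, "equal"), (10, 5, "greater"), (20, 2, "much_greater")],
    )
    def test_exposure_binning(self, c3a, c3b, expected):
        assert exposure_relation_from_lengths(c3a, c3b) == expected

    def test_exposure_bad_edges(self):
        with pytest.raises(ConfigurationError):
            exposure_relation_from_lengths(1, 1, bin_edges=(0.5, 0.4, 1.0, 2.0))
        with pytest.raises(InvalidGeometryError):
            exposure_relation_from_lengths(1, 0)

    def test_geometry_to_c1_observation(self):
        geom = grading.C1Geometry(c1a_length=10, c1b_length=5, c1a_angle=3)
        obs = grading.c1_observation_from_geometry(geom)
        assert (obs.roundness, obs.verticality) == ("flat", "horizontal")


class TestScore:
    def test_score_examples(self):
        assert ihi_score(CriterionGrades(0, 0, 0, 0, 0)) == 0.0
        assert ihi_score(CriterionGrades(2, 2, 2, 2, 2)) == 10.0
        assert ihi_score(CriterionGrades(1, 1.5, 0.5, 0, 1)) == 4.0

    def test_missing_grade_rejected(self):
        with pytest.raises(IncompleteAssessmentError):
            CriterionGrades(1, 1, 1, 0, None)
        with pytest.raises(IncompleteAssessmentError):
            CriterionGrades(1, 1, float("nan"), 0, 1)

    def test_off_grid_rejected(self):
        with pytest.raises(DataValidationError):
            CriterionGrades(0.3, 0, 0, 0, 0)
        with pytest.raises(DataValidationError):
            CriterionGrades(0, 0, 0, 1, 0)  # C4 codomain is {0, 2}

    @given(
        c1=st.sampled_from(grading.CRITERION_GRADE_SETS["c1"]),
        c2=st.sampled_from(grading.CRITERION_GRADE_SETS["c2"]),
        c3=st.sampled_from(grading.CRITERION_GRADE_SETS["c3"]),
        c4=st.sampled_from(grading.CRITERION_GRADE_SETS["c4"]),
        c5=st.sampled_from(grading.CRITERION_GRADE_SETS["c5"]),
    )
    def test_score_on_grid_and_monotone(self, c1, c2, c3, c4, c5):
        score = ihi_score(CriterionGrades(c1, c2, c3, c4, c5))
        assert 0.0 <= score <= 10.0
        assert math.isclose(score % 0.5, 0.0, abs_tol=1e-12)
        # raising any single criterion grade never lowers the score
        for crit, value in (("c1", c1), ("c2", c2), ("c3", c3)):
            if value < 2.0:
                bumped = {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5}
                bumped[crit] = value + 0.5
                assert ihi_score(CriterionGrades(**bumped)) >= score

    def test_assessment_consistency(self):
        grades = CriterionGrades(1, 1, 1, 0, 1)
        a = HippocampusAssessment("s1", "left", c0=1, grades=grades)
        assert a.score == 4.0
        with pytest.raises(DataValidationError):
            HippocampusAssessment("s1", "left", c0=1, grades=grades, score=5.0)


class TestClassification:
    @pytest.mark.parametrize(
        "score, threshold, expected",
        [(3.5, 3.75, False), (4.0, 3.75, True), (0.0, 3.75, False),
         (10.0, 3.75, True)],
    )
    def test_threshold_rule(self, score, threshold, expected):
        assert classify_hippocampus(score, threshold) is expected

    @given(st.sampled_from([x / 2 for x in range(21)]))
    def test_monotone_in_score(self, score):
        if classify_hippocampus(score, 3.75) and score < 10:
            assert classify_hippocampus(score + 0.5, 3.75)


class TestOptimalThreshold:
    def _frame(self, pairs):
        return pd.DataFrame(
            [dict(subject_id=str(i), side="left", c0=c0, score=s)
             for i, (s, c0) in enumerate(pairs)]
        )

    def test_worked_separable_example(self):
        frame = self._frame(
            [(2.0, 0), (3.0, 0), (3.5, 0), (4.0, 2), (5.0, 2)]
        )
        assert optimal_threshold(frame) == 3.75

    def test_partial_ihi_excluded_from_fit(self):
        frame = self._frame(
            [(2.0, 0), (3.0, 0), (3.5, 0), (4.0, 2), (5.0, 2),
             (9.0, 1), (9.5, 1)]  # partial IHI must not move the threshold
        )
        assert optimal_threshold(frame) == 3.75

    def test_duplication_and_permutation_invariance(self):
        base = [(2.0, 0), (3.0, 0), (3.5, 0), (4.0, 2), (5.0, 2)]
        frame = self._frame(base)
        doubled = self._frame(base + base)
        shuffled = self._frame(base[::-1])
        t = optimal_threshold(frame)
        assert optimal_threshold(doubled) == t
        assert optimal_threshold(shuffled) == t

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            optimal_threshold(self._frame([(1.0, 0), (2.0, 0)]))
        with pytest.raises(DegenerateInputError):
            optimal_threshold(self._frame([(1.0, 0), (1.0, 2)]))

    def test_tie_breaks_to_smallest_candidate(self):
        # interleaved labels: candidates 1.5 and 3.5 both reach accuracy 3/4,
        # the smaller one must be returned
        frame = self._frame([(1.0, 0), (2.0, 2), (3.0, 0), (4.0, 2)])
        assert optimal_threshold(frame) == 1.5
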