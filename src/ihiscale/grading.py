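"""Visual grading scale for incomplete hippocampal inversion (IHI).

Each hippocampus is rated on five criteria, from coronal T1 slices at the
level of the hippocampal body:

* **C1** — roundness and verticality of the body.  Segment ``C1a`` spans the
  width (medial dentate gyrus to lateral cornu Ammonis), segment ``C1b`` the
  height.  The body is *flat* (C1a > C1b), *round* (C1a = C1b) or *oval*
  (C1a < C1b), and *horizontal*, *oblique* or *vertical* by the angle of C1a.
* **C2** — depth and verticality of the collateral sulcus relative to the
  lateral limit of the hippocampus.
* **C3** — medial positioning: length of the subiculum not covered by the
  dentate gyrus (``C3a``) relative to the covered part (``C3b``), modulated
  by whether the temporal horn is emptied or filled with CSF.
* **C4** — thickness of the subiculum (bulging upward = abnormal).
* **C5** — whether the collateral or occipito-temporal sulcus rises above
  the level of the subiculum, and how vertically.

Grades lie on a 0.5 grid; their sum, the **IHI score**, ranges 0-10 and
quantifies the degree of incomplete inversion.  A global criterion **C0**
(0 = no IHI, 1 = partial, 2 = total) is rated independently and serves as
the reference when fitting the score threshold that turns the continuous
scale into a binary IHI / non-IHI classification.

The rating itself is visual: the geometric adapter functions
(:func:`classify_roundness`, :func:`classify_verticality`,
:func:`exposure_relation_from_lengths`) are a quantitative formalization for
pipelines that record landmark measurements instead of categories, with
configurable tolerances since the scale itself prescribes none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateInputError,
    IncompleteAssessmentError,
    InvalidGeometryError,
    NotApplicableError,
)

# --------------------------------------------------------------------------
# category sets and grade codomains
# --------------------------------------------------------------------------

ROUNDNESS_LEVELS = ("flat", "round", "oval")
VERTICALITY_LEVELS = ("horizontal", "oblique", "vertical")
DEPTH_RELATIONS = ("CS_less_H", "CS_equal_H", "CS_greater_H")
EXPOSURE_RELATIONS = ("much_less", "less", "equal", "greater", "much_greater")
TH_STATES = ("emptied", "filled")
CROSSING_LEVELS = ("none", "oblique_crossing", "vertical_crossing")
SIDES = ("left", "right")

HALF_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)

#: per-criterion grade codomains
CRITERION_GRADE_SETS = {
    "c1": HALF_GRID,
    "c2": HALF_GRID,
    "c3": HALF_GRID,
    "c4": (0.0, 2.0),
    "c5": (0.0, 1.0, 2.0),
}
C0_LEVELS = (0, 1, 2)

#: default tolerance (fraction of the larger segment) below which C1a and
#: C1b are considered visually equal
DEFAULT_ROUNDNESS_TOLERANCE = 0.1
#: default angular tolerance (degrees) for horizontal/vertical
DEFAULT_VERTICALITY_TOLERANCE = 10.0
#: default cutpoints on the ratio C3a/C3b separating the five exposure bins
DEFAULT_C3_BIN_EDGES = (0.25, 0.8, 1.25, 4.0)


def _check_category(value: str, allowed: Sequence[str], field: str) -> None:
    if value not in allowed:
        raise DataValidationError(
            f"{field} must be one of {allowed!r}, got {value!r}"
        )


# --------------------------------------------------------------------------
# observation types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class C1Observation:
    """Roundness and verticality of the hippocampal body."""

    roundness: str
    verticality: str

    def __post_init__(self) -> None:
        _check_category(self.roundness, ROUNDNESS_LEVELS, "roundness")
        _check_category(self.verticality, VERTICALITY_LEVELS, "verticality")


@dataclass(frozen=True)
class C1Geometry:
    """Landmark measurements behind criterion C1.

    ``c1a_length``/``c1b_length`` are the width/height segments (mm),
    ``c1a_angle`` the angle of the width segment from the horizontal.
    """

    c1a_length: float
    c1b_length: float
    c1a_angle: float

    def __post_init__(self) -> None:
        if self.c1a_length <= 0 or self.c1b_length <= 0:
            raise InvalidGeometryError("segment lengths must be strictly positive")
        if not 0.0 <= self.c1a_angle <= 90.0:
            raise InvalidGeometryError("angle must lie in [0, 90] degrees")


@dataclass(frozen=True)
class C2Observation:
    """Collateral-sulcus depth relation and verticality.

    ``depth_relation`` compares the sulcus fundus to the lateral limit of the
    hippocampus: ``CS_less_H`` (does not reach it), ``CS_equal_H`` (reaches
    it), ``CS_greater_H`` (crosses it).
    """

    depth_relation: str
    verticality: str

    def __post_init__(self) -> None:
        _check_category(self.depth_relation, DEPTH_RELATIONS, "depth_relation")
        _check_category(self.verticality, VERTICALITY_LEVELS, "verticality")


@dataclass(frozen=True)
class C3Observation:
    """Medial positioning: exposure of the subiculum and temporal-horn state."""

    exposure_relation: str
    temporal_horn: str
    c3a_visible: bool = True

    def __post_init__(self) -> None:
        _check_category(self.exposure_relation, EXPOSURE_RELATIONS, "exposure_relation")
        _check_category(self.temporal_horn, TH_STATES, "temporal_horn")
        if not self.c3a_visible and self.exposure_relation != "much_less":
            raise DataValidationError(
                "an invisible C3a segment implies exposure_relation='much_less'"
            )


@dataclass(frozen=True)
class C4Observation:
    """Subiculum thickness: abnormal when bulging upward."""

    subiculum_bulging: bool


@dataclass(frozen=True)
class C5Observation:
    """Crossing of the subiculum level by the collateral or occipito-temporal sulcus."""

    crossing: str

    def __post_init__(self) -> None:
        _check_category(self.crossing, CROSSING_LEVELS, "crossing")


# --------------------------------------------------------------------------
# geometric adapters (quantitative stand-ins for the visual judgment)
# --------------------------------------------------------------------------


def classify_roundness(
    c1a_length: float,
    c1b_length: float,
    rel_tolerance: float = DEFAULT_ROUNDNESS_TOLERANCE,
) -> str:
    """Classify the body as flat / round / oval from the width and height segments.

    The two segments count as visually equal (round) when they differ by at
    most ``rel_tolerance`` of the larger one.
    """
    if c1a_length <= 0 or c1b_length <= 0:
        raise InvalidGeometryError("segment lengths must be strictly positive")
    if not 0.0 <= rel_tolerance < 1.0:
        raise ConfigurationError("rel_tolerance must lie in [0, 1)")
    if abs(c1a_length - c1b_length) <= rel_tolerance * max(c1a_length, c1b_length):
        return "round"
    return "flat" if c1a_length > c1b_length else "oval"


def classify_verticality(
    angle: float, tol: float = DEFAULT_VERTICALITY_TOLERANCE
) -> str:
    """Classify the orientation of a segment from its angle to the horizontal.

    ``horizontal`` within ``tol`` degrees of 0, ``vertical`` within ``tol``
    of 90, ``oblique`` otherwise.
    """
    if not 0.0 <= angle <= 90.0:
        raise InvalidGeometryError("angle must lie in [0, 90] degrees")
    if not 0.0 < tol < 45.0:
        raise ConfigurationError("tol must lie in (0, 45) degrees")
    if angle <= tol:
        return "horizontal"
    if angle >= 90.0 - tol:
        return "vertical"
    return "oblique"


def exposure_relation_from_lengths(
    c3a: float,
    c3b: float,
    bin_edges: Sequence[float] = DEFAULT_C3_BIN_EDGES,
) -> str:
    """Bin the ratio C3a/C3b into the five exposure relations.

    ``c3a == 0`` (segment not visible) always maps to ``much_less``.
    """
    if c3b <= 0:
        raise InvalidGeometryError("c3b must be strictly positive")
    if c3a < 0:
        raise InvalidGeometryError("c3a must be non-negative")
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) != 4 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigurationError("bin_edges must be four strictly increasing cutpoints")
    if c3a == 0:
        return "much_less"
    r = c3a / c3b
    idx = int(np.searchsorted(edges, r, side="left"))
    return EXPOSURE_RELATIONS[idx]


def c1_observation_from_geometry(
    geometry: C1Geometry,
    rel_tolerance: float = DEFAULT_ROUNDNESS_TOLERANCE,
    angle_tolerance: float = DEFAULT_VERTICALITY_TOLERANCE,
) -> C1Observation:
    """Derive the categorical C1 observation from landmark measurements."""
    return C1Observation(
        roundness=classify_roundness(
            geometry.c1a_length, geometry.c1b_length, rel_tolerance
        ),
        verticality=classify_verticality(geometry.c1a_angle, angle_tolerance),
    )


# --------------------------------------------------------------------------
# grading tables
# --------------------------------------------------------------------------

# C1: roundness x verticality.  flat+vertical is anatomically impossible (NA).
_C1_TABLE = {
    ("flat", "horizontal"): 0.0,
    ("flat", "oblique"): 0.5,
    ("round", "horizontal"): 0.5,
    ("round", "oblique"): 1.0,
    ("round", "vertical"): 2.0,
    ("oval", "horizontal"): 1.0,
    ("oval", "oblique"): 1.5,
    ("oval", "vertical"): 2.0,
}

# C2: depth relation x verticality of the collateral sulcus.
_C2_TABLE = {
    ("CS_less_H", "horizontal"): 0.0,
    ("CS_less_H", "oblique"): 0.5,
    ("CS_less_H", "vertical"): 0.5,
    ("CS_equal_H", "horizontal"): 1.0,
    ("CS_equal_H", "oblique"): 1.0,
    ("CS_equal_H", "vertical"): 1.5,
    ("CS_greater_H", "horizontal"): 1.0,
    ("CS_greater_H", "oblique"): 1.5,
    ("CS_greater_H", "vertical"): 2.0,
}

# C3: exposure relation x temporal-horn state; the extreme relations ignore
# the temporal horn.
_C3_TABLE = {
    ("much_less", "emptied"): 2.0,
    ("much_less", "filled"): 2.0,
    ("less", "emptied"): 1.0,
    ("less", "filled"): 1.5,
    ("equal", "emptied"): 0.5,
    ("equal", "filled"): 1.0,
    ("greater", "emptied"): 0.0,
    ("greater", "filled"): 0.5,
    ("much_greater", "emptied"): 0.0,
    ("much_greater", "filled"): 0.0,
}

_C5_TABLE = {"none": 0.0, "oblique_crossing": 1.0, "vertical_crossing": 2.0}


def grade_c1(obs: C1Observation) -> float:
    """Grade criterion C1 from roundness and verticality."""
    key = (obs.roundness, obs.verticality)
    if key == ("flat", "vertical"):
        raise NotApplicableError(
            "a flat hippocampal body cannot be vertical (table cell NA)"
        )
    return _C1_TABLE[key]


def grade_c2(obs: C2Observation) -> float:
    """Grade criterion C2 from the collateral-sulcus depth relation and verticality."""
    return _C2_TABLE[(obs.depth_relation, obs.verticality)]


def grade_c3(obs: C3Observation) -> float:
    """Grade criterion C3 from subiculum exposure and temporal-horn state."""
    return _C3_TABLE[(obs.exposure_relation, obs.temporal_horn)]


def grade_c4(obs: C4Observation) -> float:
    """Grade criterion C4: 2 for a bulging (thickened) subiculum, else 0."""
    return 2.0 if obs.subiculum_bulging else 0.0


def grade_c5(obs: C5Observation) -> float:
    """Grade criterion C5 from how the fusiform-gyrus sulci cross the subiculum level."""
    return _C5_TABLE[obs.crossing]


# --------------------------------------------------------------------------
# composite score and classification
# --------------------------------------------------------------------------


def _check_grade(value: float, criterion: str) -> float:
    allowed = CRITERION_GRADE_SETS[criterion]
    v = float(value)
    if not any(math.isclose(v, a) for a in allowed):
        raise DataValidationError(
            f"{criterion} grade {value!r} not in its codomain {allowed}"
        )
    return v


@dataclass(frozen=True)
class CriterionGrades:
    """The five individual grades for one hippocampus."""

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4", "c5"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise IncompleteAssessmentError(f"grade {name} is missing")
            object.__setattr__(self, name, _check_grade(value, name))

    def as_tuple(self) -> tuple:
        return (self.c1, self.c2, self.c3, self.c4, self.c5)


def ihi_score(grades: CriterionGrades) -> float:
    """Sum of the five criterion grades; the composite IHI score in [0, 10]."""
    return float(sum(grades.as_tuple()))


def classify_hippocampus(score: float, threshold: float) -> bool:
    """Binary IHI classification: True when the score exceeds the threshold.

    Thresholds fitted by :func:`optimal_threshold` are off-grid midpoints, so
    strict comparison reproduces the score >= next-grid-value reading.
    """
    if not 0.0 <= score <= 10.0:
        raise DataValidationError("score must lie in [0, 10]")
    return score > threshold


@dataclass
class HippocampusAssessment:
    """One rated hippocampus: global criterion, grades, score, binary class."""

    subject_id: str
    side: str
    c0: int
    grades: Optional[CriterionGrades] = None
    score: Optional[float] = None
    ihi_class: Optional[bool] = None

    def __post_init__(self) -> None:
        _check_category(self.side, SIDES, "side")
        if self.c0 not in C0_LEVELS:
            raise DataValidationError(f"c0 must be in {C0_LEVELS}, got {self.c0!r}")
        if self.grades is not None:
            expected = ihi_score(self.grades)
            if self.score is None:
                self.score = expected
            elif not math.isclose(self.score, expected):
                raise DataValidationError(
                    f"score {self.score} does not equal the sum of grades {expected}"
                )


AssessmentLike = Union[pd.DataFrame, Iterable[HippocampusAssessment]]


def _scores_and_labels(assessments: AssessmentLike) -> tuple:
    """Extract (score, C0) pairs restricted to the reference classes C0 in {0, 2}."""
    if isinstance(assessments, pd.DataFrame):
        sub = assessments.loc[
            assessments["c0"].isin([0, 2]) & assessments["score"].notna()
        ]
        scores = sub["score"].to_numpy(dtype=float)
        labels = sub["c0"].to_numpy(dtype=int) == 2
    else:
        pairs = [
            (a.score, a.c0 == 2)
            for a in assessments
            if a.c0 in (0, 2) and a.score is not None
        ]
        scores = np.array([p[0] for p in pairs], dtype=float)
        labels = np.array([p[1] for p in pairs], dtype=bool)
    return scores, labels


def optimal_threshold(assessments: AssessmentLike) -> float:
    """Accuracy-maximizing score threshold against the global criterion C0.

    Only hippocampi with C0 = 0 (no IHI) or C0 = 2 (total IHI) enter the fit.
    Candidate thresholds are midpoints between consecutive distinct observed
    scores; ties in accuracy resolve to the smallest maximizing candidate, so
    the result is invariant to record order and duplication.
    """
    scores, labels = _scores_and_labels(assessments)
    if scores.size == 0 or labels.all() or not labels.any():
        raise DegenerateInputError(
            "threshold fitting needs both C0=0 and C0=2 hippocampi with scores"
        )
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise DegenerateInputError(
            "all reference scores are identical; no separating threshold exists"
        )
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    accuracies = [
        float(np.mean((scores > t) == labels)) for t in candidates
    ]
    return float(candidates[int(np.argmax(accuracies))])
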