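"""Association between IHI status and cortical sulcal morphometry.

Consumes long-format sulcal measure tables (one row per subject x hemisphere
x sulcus x measure, as exported from BrainVisa Morphologist) and compares
IHI vs non-IHI groups per (sulcus, measure) cell with pooled-variance
Student's t-tests and Cohen's d, Bonferroni-corrected over the fixed family
of 45 sulci x 5 measures x 4 association directions = 900 tests.

Group construction: subjects classified IHI on the left (resp. right)
hippocampus form the left (resp. right) IHI group; the non-IHI group holds
subjects with IHI on *neither* side, so a subject with only a contralateral
IHI enters neither set of a given comparison.  The four directions pair each
IHI side with each hemisphere's sulci (two ipsilateral, two contralateral).

Missing data are handled per cell (complete-case), and the Bonferroni
denominator stays at the design value regardless of missing cells.  The
"length" measure participates in the data model and output but is not part
of the five-measure family behind the default denominator; the report
surfaces this via the ``m`` attribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import FrozenSet, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, DegenerateInputError

MEASURES = ("surface", "max_depth", "mean_depth", "opening", "gm_thickness", "length")
#: the five measures of the planned comparison family
FAMILY_MEASURES = ("surface", "max_depth", "mean_depth", "opening", "gm_thickness")
HEMISPHERES = ("left", "right")

#: direction label -> (IHI side, hemisphere of the sulcal measures)
DIRECTIONS = {
    "leftIHI-leftHem": ("left", "left"),
    "leftIHI-rightHem": ("left", "right"),
    "rightIHI-rightHem": ("right", "right"),
    "rightIHI-leftHem": ("right", "left"),
}

#: fixed Bonferroni family size: 45 sulci x 5 measures x 4 directions
DEFAULT_BONFERRONI_M = 900


def load_nomenclature(path: Optional[str] = None) -> Tuple[str, ...]:
    """Load the sulcus label list (default: the packaged 45-label nomenclature)."""
    if path is None:
        text = (
            resources.files("ihiscale.data")
            .joinpath("sulci_nomenclature.txt")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    labels = tuple(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    if not labels:
        raise DataValidationError("sulcus nomenclature file holds no labels")
    return labels


DEFAULT_SULCI = load_nomenclature()


@dataclass(frozen=True)
class GroupAssignment:
    """Subject sets entering the association comparisons."""

    ihi_left: FrozenSet
    ihi_right: FrozenSet
    non_ihi: FrozenSet


def build_groups(assessments: pd.DataFrame, threshold: float) -> GroupAssignment:
    """Classify each subject's sides by score threshold and form the groups."""
    wide = assessments.pivot_table(
        index="subject_id", columns="side", values="score", aggfunc="first"
    )
    for side in ("left", "right"):
        if side not in wide.columns:
            wide[side] = np.nan
    left_ihi = wide.index[wide["left"] > threshold]
    right_ihi = wide.index[wide["right"] > threshold]
    either = set(left_ihi) | set(right_ihi)
    non = set(wide.dropna(subset=["left", "right"]).index) - either
    return GroupAssignment(frozenset(left_ihi), frozenset(right_ihi), frozenset(non))


def group_ttest(values_a: Sequence[float], values_b: Sequence[float]):
    """Pooled-variance two-sample Student's t-test.

    Returns ``(t, df, p_raw)``.  Zero pooled variance yields t = 0 / p = 1
    when the means agree and a signed infinite t with p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least two non-missing values")
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    if pooled_var == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, int(df), 1.0
        return float(np.sign(diff) * np.inf), int(df), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(df), float(p)


def cohens_d(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Standardized mean difference (a minus b) over the pooled SD.

    Zero pooled SD returns 0 for identical means and NaN (undefined effect)
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least two non-missing values")
    df = a.size + b.size - 2
    pooled_sd = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    diff = a.mean() - b.mean()
    if pooled_sd == 0.0:
        return 0.0 if diff == 0.0 else float("nan")
    return float(diff / pooled_sd)


def bonferroni(p_raw: float, m: int = DEFAULT_BONFERRONI_M) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p_raw <= 1.0:
        raise DataValidationError("p_raw must lie in [0, 1]")
    if m < 1:
        raise DataValidationError("m must be at least 1")
    return min(1.0, m * p_raw)


def _validate_measures(measures: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "hemisphere", "sulcus", "measure", "value"}
    missing = required - set(measures.columns)
    if missing:
        raise DataValidationError(f"sulcal table missing columns {sorted(missing)}")
    bad = ~measures["hemisphere"].isin(HEMISPHERES)
    if bad.any():
        raise DataValidationError("hemisphere must be 'left' or 'right'")
    return measures


def run_association(
    measures: pd.DataFrame,
    groups: GroupAssignment,
    alpha: float = 0.05,
    m: int = DEFAULT_BONFERRONI_M,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-(direction, sulcus, measure) group comparison.

    Returns ``(results, significant, n_skipped)`` where ``results`` has one
    row per testable cell (group means and sizes, t, df, Cohen's d, raw and
    Bonferroni-corrected p) sorted by direction, sulcus and measure;
    ``significant`` is the subset with corrected p below ``alpha``; and
    ``n_skipped`` counts cells dropped for want of at least two values per
    group.
    """
    measures = _validate_measures(measures)
    ihi_sets = {"left": groups.ihi_left, "right": groups.ihi_right}
    rows = []
    n_skipped = 0
    for direction, (ihi_side, hemisphere) in DIRECTIONS.items():
        ihi_ids = ihi_sets[ihi_side]
        if not ihi_ids or not groups.non_ihi:
            raise DegenerateInputError(
                f"empty group for direction {direction!r}"
            )
        hemi = measures.loc[measures["hemisphere"] == hemisphere]
        for (sulcus, measure), cell in hemi.groupby(["sulcus", "measure"]):
            values = cell.set_index("subject_id")["value"]
            va = values.loc[values.index.isin(ihi_ids)].to_numpy(dtype=float)
            vb = values.loc[values.index.isin(groups.non_ihi)].to_numpy(dtype=float)
            va = va[~np.isnan(va)]
            vb = vb[~np.isnan(vb)]
            if va.size < 2 or vb.size < 2:
                n_skipped += 1
                continue
            t, df, p_raw = group_ttest(va, vb)
            d = cohens_d(va, vb)
            rows.append(
                dict(direction=direction, sulcus=sulcus, measure=measure,
                     n_ihi=int(va.size), n_non_ihi=int(vb.size),
                     mean_ihi=float(va.mean()), mean_non_ihi=float(vb.mean()),
                     t=t, df=df, cohens_d=d, p_raw=p_raw,
                     p_bonf=bonferroni(p_raw, m))
            )
    results = pd.DataFrame(
        rows,
        columns=["direction", "sulcus", "measure", "n_ihi", "n_non_ihi",
                 "mean_ihi", "mean_non_ihi", "t", "df", "cohens_d",
                 "p_raw", "p_bonf"],
    )
    order = {name: i for i, name in enumerate(DIRECTIONS)}
    if not results.empty:
        results = results.sort_values(
            ["direction", "sulcus", "measure"],
            key=lambda col: col.map(order) if col.name == "direction" else col,
        ).reset_index(drop=True)
    significant = results.loc[results["p_bonf"] < alpha].reset_index(drop=True)
    results.attrs["m"] = m
    results.attrs["family_measures"] = FAMILY_MEASURES
    return results, significant, n_skipped
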