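"""Prevalence and lateralization analysis of incomplete hippocampal inversion.

Works on the cohort frame produced by the grading / simulation layers: one
row per subject x side with columns ``subject_id, side, c0, c1..c5, score``.
Provides per-side C0 frequency tables with binomial confidence intervals,
the left x right C0 co-occurrence grid, chi-square comparisons (side, sex,
handedness), per-criterion grade distributions, and score-threshold-based
IHI frequencies.

The side comparison treats left and right hippocampi of the same subjects as
independent samples, matching the original analysis; a marginal-homogeneity
(Stuart-Maxwell) variant for the methodologically paired reading is
available via ``paired=True``.  Confidence intervals default to the Wald
normal approximation (clipped to [0, 1]); Wilson intervals are available via
``method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import SquareTable
from statsmodels.stats.proportion import proportion_confint

from .errors import DataValidationError, DegenerateInputError

C0_LABELS = {0: "no_ihi", 1: "partial_ihi", 2: "total_ihi"}
C0_ORDER = ("no_ihi", "partial_ihi", "total_ihi")


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its confidence interval."""

    count: float
    n: int
    p_hat: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square independence test on a count table."""

    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    n_excluded: int = 0


def proportion_ci(
    count: float, n: int, alpha: float = 0.05, method: str = "wald"
) -> ProportionEstimate:
    """Binomial proportion with a two-sided (1 - alpha) confidence interval.

    ``method='wald'`` is the normal approximation p +/- z*sqrt(p(1-p)/n)
    clipped to [0, 1]; ``method='wilson'`` the score interval.  ``count``
    may be fractional, so an interval can be reconstructed from a published
    rounded frequency (count = reported proportion x n).
    """
    if n < 1:
        raise DegenerateInputError("n must be at least 1")
    if not 0 <= count <= n:
        raise DataValidationError("count must lie in [0, n]")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise DataValidationError("method must be 'wald' or 'wilson'")
    low, high = proportion_confint(count, n, alpha=alpha, method=sm_method)
    count_f = float(count)
    return ProportionEstimate(
        count=int(count_f) if count_f.is_integer() else count_f,
        n=int(n),
        p_hat=count / n,
        ci_low=float(np.clip(low, 0.0, 1.0)),
        ci_high=float(np.clip(high, 0.0, 1.0)),
    )


def _side_frame(assessments: pd.DataFrame, side: str) -> pd.DataFrame:
    sub = assessments.loc[assessments["side"] == side]
    if sub.empty:
        raise DegenerateInputError(f"no assessments for side {side!r}")
    return sub


def c0_frequency_table(
    assessments: pd.DataFrame,
    side: str,
    alpha: float = 0.05,
    method: str = "wald",
) -> pd.DataFrame:
    """Frequencies of no / partial / total IHI for one side, with CIs.

    Rows with missing C0 are excluded and counted in the ``n_excluded``
    attribute stored in ``DataFrame.attrs``.
    """
    sub = _side_frame(assessments, side)
    missing = int(sub["c0"].isna().sum())
    sub = sub.dropna(subset=["c0"])
    n = len(sub)
    if n == 0:
        raise DegenerateInputError(f"all C0 grades missing for side {side!r}")
    rows = []
    for level, label in C0_LABELS.items():
        count = int((sub["c0"] == level).sum())
        est = proportion_ci(count, n, alpha=alpha, method=method)
        rows.append(
            dict(category=label, count=est.count, n=est.n, p_hat=est.p_hat,
                 ci_low=est.ci_low, ci_high=est.ci_high)
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["n_excluded"] = missing
    out.attrs["side"] = side
    return out


@dataclass(frozen=True)
class CooccurrenceTable:
    """Left x right C0 co-occurrence: counts and population proportions."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n: int
    n_excluded: int


def cooccurrence_table(
    assessments: pd.DataFrame, alpha: float = 0.05, method: str = "wald"
) -> CooccurrenceTable:
    """3x3 grid of left C0 x right C0 as proportions of the population.

    Subjects missing either side's C0 are excluded (counted in
    ``n_excluded``).  Row/column count sums reproduce the per-side marginals
    exactly.
    """
    wide = assessments.pivot_table(
        index="subject_id", columns="side", values="c0", aggfunc="first"
    )
    for side in ("left", "right"):
        if side not in wide.columns:
            wide[side] = np.nan
    complete = wide.dropna(subset=["left", "right"])
    n_excluded = len(wide) - len(complete)
    n = len(complete)
    if n == 0:
        raise DegenerateInputError("no subject has both sides rated")
    counts = pd.DataFrame(0, index=list(C0_ORDER), columns=list(C0_ORDER), dtype=int)
    for li, ll in C0_LABELS.items():
        for ri, rl in C0_LABELS.items():
            counts.loc[ll, rl] = int(
                ((complete["left"] == li) & (complete["right"] == ri)).sum()
            )
    props = counts / n
    lo = props.copy()
    hi = props.copy()
    for ll in C0_ORDER:
        for rl in C0_ORDER:
            est = proportion_ci(int(counts.loc[ll, rl]), n, alpha=alpha, method=method)
            lo.loc[ll, rl] = est.ci_low
            hi.loc[ll, rl] = est.ci_high
    counts.index.name = counts.columns.name = None
    return CooccurrenceTable(counts, props, lo, hi, n, n_excluded)


def chi2_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    df_table = pd.DataFrame(table)
    arr = df_table.to_numpy(dtype=float)
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("contingency table has a zero marginal")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(df_table, float(chi2), int(dof), float(p))


def _c0_counts(sub: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {label: int((sub["c0"] == level).sum()) for level, label in C0_LABELS.items()}
    )


def side_comparison(
    assessments: pd.DataFrame, paired: bool = False
) -> ContingencyResult:
    """Left vs right distribution of C0.

    The default stacks the two sides as independent samples (2x3 chi-square),
    as in the original analysis.  ``paired=True`` runs a Stuart-Maxwell
    marginal-homogeneity test on the subject-level left x right table instead.
    """
    if paired:
        co = cooccurrence_table(assessments)
        res = SquareTable(co.counts.to_numpy(dtype=float)).homogeneity()
        return ContingencyResult(
            co.counts, float(res.statistic), int(res.df), float(res.pvalue),
            n_excluded=co.n_excluded,
        )
    table = pd.DataFrame(
        {
            side: _c0_counts(_side_frame(assessments, side).dropna(subset=["c0"]))
            for side in ("left", "right")
        }
    ).T
    return chi2_independence(table)


def covariate_comparison(
    assessments: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate: str,
    side: str,
) -> ContingencyResult:
    """Chi-square comparison of the C0 distribution across covariate levels.

    Subjects with a missing covariate are excluded listwise and counted in
    ``n_excluded``.
    """
    if covariate not in covariates.columns:
        raise DataValidationError(f"covariates table has no column {covariate!r}")
    sub = _side_frame(assessments, side).dropna(subset=["c0"])
    merged = sub.merge(covariates[["subject_id", covariate]], on="subject_id", how="left")
    n_before = len(merged)
    merged = merged.dropna(subset=[covariate])
    n_excluded = n_before - len(merged)
    levels = sorted(merged[covariate].unique())
    if len(levels) < 2:
        raise DegenerateInputError(
            f"covariate {covariate!r} has fewer than two observed levels"
        )
    table = pd.DataFrame(
        {level: _c0_counts(merged.loc[merged[covariate] == level]) for level in levels}
    ).T
    table = table.loc[:, (table.sum(axis=0) > 0)]
    result = chi2_independence(table)
    return ContingencyResult(result.table, result.chi2, result.df, result.p,
                             n_excluded=n_excluded)


def sex_comparison(assessments, covariates, side) -> ContingencyResult:
    """C0 distribution of males vs females for one side."""
    return covariate_comparison(assessments, covariates, "sex", side)


def handedness_comparison(assessments, covariates, side) -> ContingencyResult:
    """C0 distribution across handedness groups for one side."""
    return covariate_comparison(assessments, covariates, "handedness", side)


def criterion_distribution(
    assessments: pd.DataFrame, alpha: float = 0.05
) -> Tuple[pd.DataFrame, dict]:
    """Grade frequencies per criterion per side, and left-vs-right tests.

    Returns a long frequency frame (criterion, side, grade, count, p_hat,
    CI bounds) and a dict criterion -> :class:`ContingencyResult` comparing
    the two sides' grade distributions (grades unobserved on both sides are
    dropped from the test table, since their expected counts are zero).
    """
    from .grading import CRITERION_GRADE_SETS

    rows = []
    tests = {}
    for criterion, grade_set in CRITERION_GRADE_SETS.items():
        per_side = {}
        for side in ("left", "right"):
            sub = _side_frame(assessments, side).dropna(subset=[criterion])
            n = len(sub)
            counts = {g: int(np.isclose(sub[criterion], g).sum()) for g in grade_set}
            per_side[side] = counts
            for g, count in counts.items():
                est = proportion_ci(count, n, alpha=alpha)
                rows.append(
                    dict(criterion=criterion, side=side, grade=g, count=count,
                         n=n, p_hat=est.p_hat, ci_low=est.ci_low,
                         ci_high=est.ci_high)
                )
        table = pd.DataFrame(per_side).T
        table = table.loc[:, table.sum(axis=0) > 0]
        tests[criterion] = chi2_independence(table)
    return pd.DataFrame(rows), tests


def threshold_frequency_table(
    assessments: pd.DataFrame,
    threshold: float,
    mode: str = "classify_all",
    alpha: float = 0.05,
    method: str = "wald",
) -> pd.DataFrame:
    """IHI / no-IHI frequencies per side under the fitted score threshold.

    ``mode='classify_all'`` classifies every hippocampus by its score.
    ``mode='exclude_partial'`` classifies only hippocampi with C0 in {0, 2}
    but keeps the whole side population as denominator, so the two class
    frequencies leave out the partial-IHI share (the "fixing the partial"
    reading).  Rows with missing scores are excluded and reported via
    ``DataFrame.attrs['n_excluded']``.
    """
    if mode not in ("classify_all", "exclude_partial"):
        raise DataValidationError("mode must be 'classify_all' or 'exclude_partial'")
    rows = []
    excluded = {}
    for side in ("left", "right"):
        sub = _side_frame(assessments, side)
        missing = int(sub["score"].isna().sum())
        sub = sub.dropna(subset=["score"])
        n = len(sub)
        if n == 0:
            raise DegenerateInputError(f"no scores available for side {side!r}")
        excluded[side] = missing
        classified = sub if mode == "classify_all" else sub.loc[sub["c0"] != 1]
        ihi_count = int((classified["score"] > threshold).sum())
        no_count = len(classified) - ihi_count
        for label, count in (("ihi", ihi_count), ("no_ihi", no_count)):
            est = proportion_ci(count, n, alpha=alpha, method=method)
            rows.append(
                dict(side=side, category=label, count=count, n=n,
                     p_hat=est.p_hat, ci_low=est.ci_low, ci_high=est.ci_high)
            )
    out = pd.DataFrame(rows).set_index(["side", "category"])
    out.attrs["n_excluded"] = excluded
    out.attrs["mode"] = mode
    out.attrs["threshold"] = threshold
    return out
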