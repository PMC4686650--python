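"""Intra- and inter-observer agreement for the IHI visual scale.

Two trained observers each rated the same reproducibility series twice, so
agreement is summarized per criterion over four comparisons (two intra-rater,
two inter-rater).  Criteria with nominal or two-level codomains (C0, C4, C5)
use Cohen's kappa; criteria with graded ordinal codomains (C1, C2, C3) use a
weighted kappa with linear disagreement weights ``|i - j| / (k - 1)`` over
category ranks, which penalizes a half-grade slip less than a two-grade one
and reduces to plain kappa for two categories.

Standard errors follow the large-sample (Fleiss-Cohen-Everitt) form with a
normal 95% interval; a seeded bootstrap percentile interval is available as
an alternative.  Confusion tables are always built over the criterion's full
fixed category set, keeping unobserved categories so that chance agreement
(and the weight matrix) refer to the scale, not to the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, UndefinedKappaError
from .grading import C0_LEVELS, CRITERION_GRADE_SETS

#: category set per criterion, ordered (ordinal rank = position)
CRITERION_CATEGORIES = {
    "C0": tuple(float(v) for v in C0_LEVELS),
    "C1": CRITERION_GRADE_SETS["c1"],
    "C2": CRITERION_GRADE_SETS["c2"],
    "C3": CRITERION_GRADE_SETS["c3"],
    "C4": CRITERION_GRADE_SETS["c4"],
    "C5": CRITERION_GRADE_SETS["c5"],
}

#: weighting used in the study design, per criterion
CRITERION_WEIGHTING = {
    "C0": "none",
    "C1": "linear",
    "C2": "linear",
    "C3": "linear",
    "C4": "none",
    "C5": "none",
}

#: the four rating-session comparisons of the two-observer design
COMPARISONS = ("A1_vs_A2", "B1_vs_B2", "A1_vs_B1", "A2_vs_B2")


@dataclass(frozen=True)
class RatingSeriesPair:
    """Two raters' grades for the same ordered series of items."""

    item_ids: Tuple
    rater_a: Tuple
    rater_b: Tuple
    categories: Tuple

    def __post_init__(self) -> None:
        if not (len(self.item_ids) == len(self.rater_a) == len(self.rater_b)):
            raise DataValidationError("item_ids, rater_a and rater_b must align")
        if len(self.item_ids) < 2:
            raise DataValidationError("agreement needs at least two rated items")
        for series in (self.rater_a, self.rater_b):
            for g in series:
                if g not in self.categories:
                    raise DataValidationError(
                        f"grade {g!r} not in category set {self.categories}"
                    )


@dataclass(frozen=True)
class KappaResult:
    """Agreement statistic with its standard error and 95% interval."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    weighting: str
    n: int


def confusion_table(pair: RatingSeriesPair) -> pd.DataFrame:
    """Square count matrix: rows rater A, columns rater B, over the full category set."""
    cats = list(pair.categories)
    table = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for a, b in zip(pair.rater_a, pair.rater_b):
        table.loc[a, b] += 1
    return table


def _agreement_weights(k: int, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.eye(k)
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    if weighting == "linear":
        return 1.0 - d
    if weighting == "quadratic":
        return 1.0 - d**2
    raise DataValidationError(f"unknown weighting {weighting!r}")


def _as_array(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DataValidationError("confusion table must be square")
    if arr.sum() < 2:
        raise DataValidationError("confusion table must hold at least two items")
    return arr


def _kappa_from_counts(
    counts: np.ndarray, weighting: str, alpha: float = 0.05
) -> KappaResult:
    """Weighted kappa with large-sample SE from a square count matrix.

    Uses agreement weights w (identity for plain kappa); the point estimate
    equals the disagreement-weight formulation 1 - sum(v o)/sum(v e) with
    v = 1 - w.
    """
    n = counts.sum()
    p = counts / n
    k = counts.shape[0]
    w = _agreement_weights(k, weighting)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if np.isclose(pe, 1.0):
        raise UndefinedKappaError(
            "chance agreement is 1 (both raters constant and identical); "
            "kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa
    w_row = w @ col          # E_j[w_ij] over rater-B marginal
    w_col = w.T @ row        # E_i[w_ij] over rater-A marginal
    term = (w * (1.0 - pe) - (w_row[:, None] + w_col[None, :]) * (1.0 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2.0 * pe + po) ** 2) / (
        n * (1.0 - pe) ** 4
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci_low = max(-1.0, kappa - z * se)
    ci_high = min(1.0, kappa + z * se)
    return KappaResult(float(kappa), se, float(ci_low), float(ci_high),
                       weighting, int(round(n)))


def cohen_kappa(table, alpha: float = 0.05) -> KappaResult:
    """Unweighted Cohen's kappa from a square count matrix."""
    return _kappa_from_counts(_as_array(table), "none", alpha)


def weighted_kappa(table, weighting: str = "linear", alpha: float = 0.05) -> KappaResult:
    """Weighted kappa (linear by default, quadratic via ``weighting``)."""
    if weighting not in ("linear", "quadratic"):
        raise DataValidationError("weighting must be 'linear' or 'quadratic'")
    return _kappa_from_counts(_as_array(table), weighting, alpha)


def kappa_for_pair(
    pair: RatingSeriesPair,
    weighting: str = "none",
    alpha: float = 0.05,
    ci_method: str = "asymptotic",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> KappaResult:
    """Kappa for a rating-series pair, with asymptotic or bootstrap CI."""
    table = confusion_table(pair)
    result = _kappa_from_counts(_as_array(table), weighting, alpha)
    if ci_method == "asymptotic":
        return result
    if ci_method != "bootstrap":
        raise DataValidationError("ci_method must be 'asymptotic' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    a = np.asarray(pair.rater_a, dtype=float)
    b = np.asarray(pair.rater_b, dtype=float)
    cats = {c: i for i, c in enumerate(pair.categories)}
    ai = np.array([cats[v] for v in pair.rater_a])
    bi = np.array([cats[v] for v in pair.rater_b])
    k = len(pair.categories)
    estimates = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(ai), size=len(ai))
        counts = np.zeros((k, k))
        np.add.at(counts, (ai[idx], bi[idx]), 1.0)
        try:
            estimates.append(_kappa_from_counts(counts, weighting, alpha).kappa)
        except UndefinedKappaError:
            continue
    if not estimates:
        raise UndefinedKappaError("all bootstrap resamples had undefined kappa")
    lo, hi = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return KappaResult(result.kappa, result.se, float(lo), float(hi),
                       weighting, result.n)


def reproducibility_report(
    pairs: Mapping[Tuple[str, str], RatingSeriesPair],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Agreement per (criterion, comparison), one row each.

    ``pairs`` maps (criterion, comparison) -> :class:`RatingSeriesPair`.
    Criteria whose series are constant and identical across both raters (as
    happens when a rare feature never occurs in the reproducibility sample)
    are flagged not-evaluable instead of being assigned a kappa.
    """
    rows = []
    for (criterion, comparison), pair in pairs.items():
        weighting = CRITERION_WEIGHTING.get(criterion, "none")
        try:
            res = kappa_for_pair(pair, weighting=weighting, alpha=alpha)
            rows.append(
                dict(criterion=criterion, comparison=comparison, evaluable=True,
                     kappa=res.kappa, se=res.se, ci_low=res.ci_low,
                     ci_high=res.ci_high, weighting=weighting, n=res.n)
            )
        except UndefinedKappaError:
            rows.append(
                dict(criterion=criterion, comparison=comparison, evaluable=False,
                     kappa=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                     weighting=weighting, n=len(pair.item_ids))
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["criterion", "comparison"]).reset_index(drop=True)


def pairs_from_table(
    ratings: pd.DataFrame,
    criterion_categories: Optional[Mapping[str, Sequence[float]]] = None,
) -> Mapping[Tuple[str, str], RatingSeriesPair]:
    """Build comparison pairs from a long reliability table.

    Expects columns ``item_id, criterion, rater, session, grade`` with two
    raters and two sessions.  Produces the four standard comparisons
    (each rater's session 1 vs 2, and inter-rater within each session).
    """
    required = {"item_id", "criterion", "rater", "session", "grade"}
    missing = required - set(ratings.columns)
    if missing:
        raise DataValidationError(f"reliability table missing columns {sorted(missing)}")
    cats = dict(CRITERION_CATEGORIES)
    if criterion_categories:
        cats.update({k: tuple(v) for k, v in criterion_categories.items()})
    raters = sorted(ratings["rater"].unique())
    sessions = sorted(ratings["session"].unique())
    if len(raters) != 2 or len(sessions) != 2:
        raise DataValidationError("expected exactly two raters and two sessions")
    ra, rb = raters
    s1, s2 = sessions
    comparisons = {
        "A1_vs_A2": ((ra, s1), (ra, s2)),
        "B1_vs_B2": ((rb, s1), (rb, s2)),
        "A1_vs_B1": ((ra, s1), (rb, s1)),
        "A2_vs_B2": ((ra, s2), (rb, s2)),
    }
    out = {}
    for criterion, sub in ratings.groupby("criterion"):
        if criterion not in cats:
            raise DataValidationError(f"unknown criterion {criterion!r}")
        wide = sub.pivot_table(
            index="item_id", columns=["rater", "session"], values="grade",
            aggfunc="first",
        )
        for name, (ka, kb) in comparisons.items():
            if ka not in wide.columns or kb not in wide.columns:
                continue
            aligned = wide[[ka, kb]].dropna()
            out[(criterion, name)] = RatingSeriesPair(
                item_ids=tuple(aligned.index),
                rater_a=tuple(float(v) for v in aligned[ka]),
                rater_b=tuple(float(v) for v in aligned[kb]),
                categories=tuple(cats[criterion]),
            )
    return out
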