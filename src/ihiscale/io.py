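"""Readers, writers, configuration and the end-to-end pipeline.

Three CSV schemas (UTF-8, comma-separated, ``.`` decimals, header required):

* ratings — one row per subject x side: ``subject_id, side, c0, c1..c5``
  (grades on the 0.5 grid, may be empty) plus optional raw-observation
  columns (``c1a_mm, c1b_mm, c1_angle_deg, c2_depth_relation,
  c2_verticality, c3a_mm, c3b_mm, th_state, c4_bulging, c5_crossing``) from
  which missing grades are computed;
* covariates — ``subject_id, sex, age_years, handedness``;
* sulcal — long format ``subject_id, hemisphere, sulcus, measure, value``.

Row-level problems (off-grid grade, unknown category) are collected as
:class:`RowError` records rather than silently dropped; structural problems
(missing columns, duplicated keys) raise :class:`~ihiscale.errors.SchemaError`.
Grades are written as one-decimal strings so a write/read round trip is
lossless on the 0.5 grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import grading, prevalence, reliability, sulcal
from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateInputError,
    SchemaError,
)

logger = logging.getLogger("ihiscale")

RATINGS_COLUMNS = ["subject_id", "side", "c0", "c1", "c2", "c3", "c4", "c5"]
OBSERVATION_COLUMNS = [
    "c1a_mm", "c1b_mm", "c1_angle_deg", "c2_depth_relation", "c2_verticality",
    "c3a_mm", "c3b_mm", "th_state", "c4_bulging", "c5_crossing",
]
COVARIATE_COLUMNS = ["subject_id", "sex", "age_years", "handedness"]
SULCAL_COLUMNS = ["subject_id", "hemisphere", "sulcus", "measure", "value"]
RELIABILITY_COLUMNS = ["item_id", "criterion", "rater", "session", "grade"]


@dataclass(frozen=True)
class RowError:
    """One rejected row: CSV line number (1-based, header = 1) and reason."""

    line: int
    message: str


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing columns {missing}")


def _grades_from_observations(row: pd.Series) -> Dict[str, float]:
    """Compute any missing grades of one row from its raw observations."""
    out: Dict[str, float] = {}
    if pd.isna(row.get("c1")):
        if not pd.isna(row.get("c1a_mm")):
            geom = grading.C1Geometry(
                float(row["c1a_mm"]), float(row["c1b_mm"]), float(row["c1_angle_deg"])
            )
            out["c1"] = grading.grade_c1(grading.c1_observation_from_geometry(geom))
    if pd.isna(row.get("c2")) and not pd.isna(row.get("c2_depth_relation")):
        out["c2"] = grading.grade_c2(
            grading.C2Observation(str(row["c2_depth_relation"]), str(row["c2_verticality"]))
        )
    if pd.isna(row.get("c3")) and not pd.isna(row.get("c3a_mm")):
        relation = grading.exposure_relation_from_lengths(
            float(row["c3a_mm"]), float(row["c3b_mm"])
        )
        out["c3"] = grading.grade_c3(
            grading.C3Observation(
                relation, str(row["th_state"]), c3a_visible=float(row["c3a_mm"]) > 0
            )
        )
    if pd.isna(row.get("c4")) and not pd.isna(row.get("c4_bulging")):
        bulging = str(row["c4_bulging"]).strip().lower() in ("true", "1", "yes")
        out["c4"] = grading.grade_c4(grading.C4Observation(bulging))
    if pd.isna(row.get("c5")) and not pd.isna(row.get("c5_crossing")):
        out["c5"] = grading.grade_c5(grading.C5Observation(str(row["c5_crossing"])))
    return out


def read_ratings(path) -> Tuple[pd.DataFrame, List[RowError]]:
    """Read and validate a ratings CSV; returns (valid rows, row errors).

    Missing grades are computed from raw-observation columns where present;
    the ``score`` column is (re)computed as the sum of grades when all five
    are available.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "side"], "ratings")
    for col in RATINGS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    dup = df.duplicated(subset=["subject_id", "side"], keep=False)
    if dup.any():
        dup_keys = df.loc[dup, ["subject_id", "side"]].drop_duplicates()
        raise SchemaError(
            f"duplicated (subject_id, side) pairs: {dup_keys.to_records(index=False).tolist()}"
        )
    errors: List[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    grade_cols = ["c1", "c2", "c3", "c4", "c5"]
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            if row["side"] not in grading.SIDES:
                raise DataValidationError(f"side {row['side']!r} not in {grading.SIDES}")
            if not pd.isna(row["c0"]):
                c0 = float(row["c0"])
                if c0 not in (0.0, 1.0, 2.0):
                    raise DataValidationError(f"c0 {row['c0']!r} not in {{0, 1, 2}}")
            computed = _grades_from_observations(row)
            for crit, value in computed.items():
                df.loc[i, crit] = value
            for crit in grade_cols:
                value = df.loc[i, crit]
                if not pd.isna(value):
                    allowed = grading.CRITERION_GRADE_SETS[crit]
                    if not any(np.isclose(float(value), a) for a in allowed):
                        raise DataValidationError(
                            f"{crit} grade {value!r} off the grid {allowed}"
                        )
        except DataValidationError as exc:
            errors.append(RowError(line=line, message=str(exc)))
            keep[df.index.get_loc(i)] = False
    out = df.loc[keep].copy()
    out["c0"] = out["c0"].astype(float).astype("Int64")
    have_all = out[grade_cols].notna().all(axis=1)
    out.loc[have_all, "score"] = out.loc[have_all, grade_cols].astype(float).sum(axis=1)
    if "score" not in out.columns:
        out["score"] = np.nan
    logger.info("read_ratings: %d rows kept, %d rejected", len(out), len(errors))
    return out[RATINGS_COLUMNS + ["score"]].reset_index(drop=True), errors


def read_covariates(path) -> Tuple[pd.DataFrame, List[RowError]]:
    """Read and validate a covariates CSV; returns (valid rows, row errors)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id"], "covariates")
    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df.duplicated(subset=["subject_id"]).any():
        raise SchemaError("duplicated subject_id in covariates")
    errors: List[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        line = i + 2
        if not pd.isna(row["sex"]) and row["sex"] not in ("F", "M"):
            errors.append(RowError(line, f"sex {row['sex']!r} not in {{'F', 'M'}}"))
            keep[i] = False
        elif not pd.isna(row["handedness"]) and row["handedness"] not in (
            "right", "left", "both",
        ):
            errors.append(
                RowError(line, f"handedness {row['handedness']!r} unknown")
            )
            keep[i] = False
    out = df.loc[keep, COVARIATE_COLUMNS].reset_index(drop=True)
    logger.info("read_covariates: %d rows kept, %d rejected", len(out), len(errors))
    return out, errors


def read_sulcal(path) -> Tuple[pd.DataFrame, List[RowError]]:
    """Read and validate a long-format sulcal measures CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, SULCAL_COLUMNS, "sulcal")
    if df.duplicated(subset=["subject_id", "hemisphere", "sulcus", "measure"]).any():
        raise SchemaError("duplicated (subject, hemisphere, sulcus, measure) rows")
    errors: List[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    bad_hemi = ~df["hemisphere"].isin(sulcal.HEMISPHERES)
    bad_measure = ~df["measure"].isin(sulcal.MEASURES)
    bad_value = ~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))
    for mask, what in ((bad_hemi, "hemisphere"), (bad_measure, "measure"),
                       (bad_value, "value")):
        for i in df.index[mask & keep]:
            errors.append(RowError(i + 2, f"invalid {what}: {df.loc[i, what]!r}"))
            keep[i] = False
    out = df.loc[keep, SULCAL_COLUMNS].reset_index(drop=True)
    out["value"] = out["value"].astype(float)
    logger.info("read_sulcal: %d rows kept, %d rejected", len(out), len(errors))
    return out, errors


def read_reliability(path) -> pd.DataFrame:
    """Read a long reliability ratings CSV (item, criterion, rater, session, grade)."""
    df = pd.read_csv(path)
    _require_columns(df, RELIABILITY_COLUMNS, "reliability")
    return df


def _format_grades(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("c1", "c2", "c3", "c4", "c5", "score"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.1f}"
            )
    return out


def write_ratings(df: pd.DataFrame, path) -> None:
    """Write a ratings table with grades as one-decimal strings."""
    _format_grades(df).to_csv(path, index=False)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_sulcal(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def frame_to_markdown(df: pd.DataFrame, float_fmt: str = "{:.4g}") -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""
    table = df.reset_index() if df.index.name or isinstance(
        df.index, pd.MultiIndex
    ) or df.index.dtype == object else df

    def fmt(v):
        if isinstance(v, float):
            return float_fmt.format(v)
        return str(v)

    headers = [str(c) for c in table.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end analysis configuration (YAML-serializable)."""

    ratings_path: Optional[str] = None
    covariates_path: Optional[str] = None
    sulcal_path: Optional[str] = None
    reliability_path: Optional[str] = None
    output_dir: str = "ihiscale_output"
    threshold: Union[str, float] = "fit"
    alpha: float = 0.05
    bonferroni_m: int = sulcal.DEFAULT_BONFERRONI_M
    seed: int = 0
    roundness_tolerance: float = grading.DEFAULT_ROUNDNESS_TOLERANCE
    verticality_tolerance: float = grading.DEFAULT_VERTICALITY_TOLERANCE
    c3_bin_edges: Tuple[float, ...] = grading.DEFAULT_C3_BIN_EDGES

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.bonferroni_m < 1:
            raise ConfigurationError("bonferroni_m must be at least 1")
        if self.threshold != "fit":
            try:
                self.threshold = float(self.threshold)
            except (TypeError, ValueError):
                raise ConfigurationError(
                    "threshold must be 'fit' or a number"
                ) from None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("pipeline config must be a YAML mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _config_hash(config) -> str:
    """Stable short hash of any config dataclass (provenance stamping).

    File locations identify where data lives, not what the analysis does,
    so path fields are left out.
    """
    skip = {"output_dir", "ratings_path", "covariates_path", "sulcal_path",
            "reliability_path"}
    payload = json.dumps(
        {k: getattr(config, k) for k in config.__dataclass_fields__
         if k not in skip},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run every analysis stage the configured inputs support.

    Writes CSV + markdown analogs of the reproducibility, prevalence,
    co-occurrence, grade-distribution, threshold-frequency and association
    tables into ``config.output_dir``, plus ``exclusions.json`` and a
    ``provenance.json`` (seed, config hash, version).  Returns the mapping
    of artifact name -> path.  Deterministic given identical inputs and
    configuration.
    """
    if config.ratings_path is None:
        raise ConfigurationError("pipeline stage 'load': ratings_path is required")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    exclusions: Dict[str, object] = {}

    ratings, rating_errors = read_ratings(config.ratings_path)
    exclusions["ratings_rows_rejected"] = [
        {"line": e.line, "message": e.message} for e in rating_errors
    ]
    logger.info("pipeline: %d assessment rows", len(ratings))

    if config.threshold == "fit":
        threshold = grading.optimal_threshold(ratings)
        logger.info("pipeline: fitted score threshold %.2f", threshold)
    else:
        threshold = float(config.threshold)

    def emit(name: str, frame: pd.DataFrame) -> None:
        csv_path = out_dir / f"{name}.csv"
        frame.to_csv(csv_path, float_format="%.6g")
        (out_dir / f"{name}.md").write_text(
            frame_to_markdown(frame.reset_index()), encoding="utf-8"
        )
        artifacts[name] = csv_path

    # reliability stage (optional input)
    if config.reliability_path:
        rel_table = read_reliability(config.reliability_path)
        pairs = reliability.pairs_from_table(rel_table)
        emit("reliability", reliability.reproducibility_report(pairs, config.alpha))

    # prevalence stages
    freq_frames = []
    for side in ("left", "right"):
        t = prevalence.c0_frequency_table(ratings, side, alpha=config.alpha)
        t.insert(0, "side", side)
        freq_frames.append(t)
        exclusions[f"c0_missing_{side}"] = t.attrs["n_excluded"]
    emit("c0_frequency", pd.concat(freq_frames))

    co = prevalence.cooccurrence_table(ratings, alpha=config.alpha)
    exclusions["cooccurrence_subjects_excluded"] = co.n_excluded
    emit("c0_cooccurrence_counts", co.counts)
    emit("c0_cooccurrence_proportions", co.proportions)

    side_res = prevalence.side_comparison(ratings)
    grade_freq, grade_tests = prevalence.criterion_distribution(
        ratings, alpha=config.alpha
    )
    emit("grade_distribution", grade_freq.set_index(["criterion", "side", "grade"]))
    tests_frame = pd.DataFrame(
        [dict(comparison="side_c0", chi2=side_res.chi2, df=side_res.df, p=side_res.p)]
        + [
            dict(comparison=f"side_{crit}", chi2=r.chi2, df=r.df, p=r.p)
            for crit, r in grade_tests.items()
        ]
    )
    if config.covariates_path:
        covariates, cov_errors = read_covariates(config.covariates_path)
        exclusions["covariate_rows_rejected"] = [
            {"line": e.line, "message": e.message} for e in cov_errors
        ]
        extra = []
        for covariate in ("sex", "handedness"):
            for side in ("left", "right"):
                res = prevalence.covariate_comparison(
                    ratings, covariates, covariate, side
                )
                extra.append(
                    dict(comparison=f"{covariate}_{side}", chi2=res.chi2,
                         df=res.df, p=res.p)
                )
                exclusions[f"{covariate}_missing_{side}"] = res.n_excluded
        tests_frame = pd.concat(
            [tests_frame, pd.DataFrame(extra)], ignore_index=True
        )
    emit("chi2_tests", tests_frame.set_index("comparison"))

    thr_frames = []
    for mode in ("exclude_partial", "classify_all"):
        t = prevalence.threshold_frequency_table(
            ratings, threshold, mode=mode, alpha=config.alpha
        )
        t.insert(0, "mode", mode)
        thr_frames.append(t)
    emit("threshold_frequency", pd.concat(thr_frames))

    # association stage (optional input)
    if config.sulcal_path:
        if not Path(config.sulcal_path).exists():
            raise DataValidationError(
                f"pipeline stage 'associate': sulcal file not found: {config.sulcal_path}"
            )
        measures, sulcal_errors = read_sulcal(config.sulcal_path)
        exclusions["sulcal_rows_rejected"] = [
            {"line": e.line, "message": e.message} for e in sulcal_errors
        ]
        groups = sulcal.build_groups(ratings, threshold)
        results, significant, n_skipped = sulcal.run_association(
            measures, groups, alpha=config.alpha, m=config.bonferroni_m
        )
        exclusions["association_cells_skipped"] = n_skipped
        emit("association", results.set_index(["direction", "sulcus", "measure"]))
        emit(
            "association_significant",
            significant.set_index(["direction", "sulcus", "measure"]),
        )

    exclusions_path = out_dir / "exclusions.json"
    exclusions_path.write_text(
        json.dumps(exclusions, indent=2, sort_keys=True), encoding="utf-8"
    )
    artifacts["exclusions"] = exclusions_path
    from . import __version__

    provenance = {
        "seed": config.seed,
        "threshold": threshold,
        "config_hash": _config_hash(config),
        "version": __version__,
    }
    provenance_path = out_dir / "provenance.json"
    provenance_path.write_text(
        json.dumps(provenance, indent=2, sort_keys=True), encoding="utf-8"
    )
    artifacts["provenance"] = provenance_path
    return artifacts
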