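"""Group construction, t-test/effect-size oracles and the association scan."""

import numpy as np
import pandas as pd
import pytest

from ihiscale.errors import DataValidationError, DegenerateInputError
from ihiscale.simulate import (
    GeneratorConfig,
    SulcalEffect,
    generate_assessments,
    generate_sulcal_measures,
)
from ihiscale.sulcal import (
    DEFAULT_BONFERRONI_M,
    DEFAULT_SULCI,
    DIRECTIONS,
    FAMILY_MEASURES,
    GroupAssignment,
    bonferroni,
    build_groups,
    cohens_d,
    group_ttest,
    load_nomenclature,
    run_association,
)


def brute_force_t_and_d(a, b):
    """Textbook pooled-variance formulas as an independent oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return t, d


def _ratings(score_pairs):
    rows = []
    for i, (left, right) in enumerate(score_pairs):
        rows.append(dict(subject_id=f"s{i}", side="left", c0=0, score=left))
        rows.append(dict(subject_id=f"s{i}", side="right", c0=0, score=right))
    return pd.DataFrame(rows)


class TestGroups:
    def test_toy_set_logic(self):
        frame = _ratings([(5.0, 1.0), (1.0, 5.0), (5.0, 5.0), (1.0, 1.0)])
        groups = build_groups(frame, 3.75)
        assert groups.ihi_left == {"s0", "s2"}
        assert groups.ihi_right == {"s1", "s2"}
        assert groups.non_ihi == {"s3"}

    def test_no_ihi_anywhere(self):
        frame = _ratings([(1.0, 1.0), (2.0, 3.0)])
        groups = build_groups(frame, 3.75)
        assert groups.ihi_left == frozenset()
        assert groups.non_ihi == {"s0", "s1"}


class TestTTestAndEffectSize:
    @pytest.mark.parametrize(
        "a, b",
        [([1, 2, 3], [2, 3, 4]),
         ([1.2, 0.8, 1.1, 0.9], [2.0, 2.2, 1.8]),
         (list(range(10)), [0.5, 2.5, 7.0, 9.0])],
    )
    def test_oracle_equivalence(self, a, b):
        t, df, p = group_ttest(a, b)
        t_ref, d_ref = brute_force_t_and_d(a, b)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == len(a) + len(b) - 2
        assert cohens_d(a, b) == pytest.approx(d_ref, rel=1e-12)

    def test_identical_groups(self):
        t, _, p = group_ttest([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_t_d_relation(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 1, 9)
        t, _, _ = group_ttest(a, b)
        assert cohens_d(a, b) == pytest.approx(
            t * np.sqrt(1 / len(a) + 1 / len(b)), rel=1e-12
        )

    def test_zero_variance_branches(self):
        t, _, p = group_ttest([1, 1, 1], [1, 1])
        assert (t, p) == (0.0, 1.0)
        t, _, p = group_ttest([2, 2, 2], [1, 1])
        assert np.isinf(t) and t > 0 and p == 0.0
        assert np.isnan(cohens_d([2, 2, 2], [1, 1]))

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_ttest([1], [1, 2])

    def test_missing_values_dropped(self):
        t1, _, _ = group_ttest([1, 2, np.nan, 3], [2, 3, 4])
        t2, _, _ = group_ttest([1, 2, 3], [2, 3, 4])
        assert t1 == pytest.approx(t2)

    def test_null_calibration(self):
        # pooled t-test on null normal data rejects at about the nominal rate
        rng = np.random.default_rng(17)
        n_rej = 0
        reps = 1000
        for _ in range(reps):
            _, _, p = group_ttest(rng.normal(size=20), rng.normal(size=25))
            n_rej += p < 0.05
        assert 0.03 <= n_rej / reps <= 0.07


class TestBonferroni:
    def test_values(self):
        assert bonferroni(1e-8, 900) == pytest.approx(9e-6)
        assert bonferroni(0.5, 900) == 1.0
        assert bonferroni(0.05 / 900, 900) == pytest.approx(0.05)

    def test_family_size_constant(self):
        assert len(DEFAULT_SULCI) * len(FAMILY_MEASURES) * len(DIRECTIONS) == 900
        assert DEFAULT_BONFERRONI_M == 900

    def test_invalid(self):
        with pytest.raises(DataValidationError):
            bonferroni(1.2, 900)
        with pytest.raises(DataValidationError):
            bonferroni(0.5, 0)


class TestNomenclature:
    def test_packaged_labels(self):
        labels = load_nomenclature()
        assert len(labels) == 45
        for required in ("F.Cal.", "F.Coll.", "S.Call.", "S.Li.",
                         "S.O.T.lat.ant.", "S.C."):
            assert required in labels


def _measures(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "hemisphere", "sulcus", "measure", "value"]
    )


class TestRunAssociation:
    def _toy(self, shift=2.0, n=12):
        rng = np.random.default_rng(9)
        ihi = {f"i{k}" for k in range(n)}
        non = {f"n{k}" for k in range(n)}
        groups = GroupAssignment(frozenset(ihi), frozenset(ihi), frozenset(non))
        rows = []
        for sid in sorted(ihi | non):
            for hemi in ("left", "right"):
                base = shift if sid.startswith("i") else 0.0
                rows.append([sid, hemi, "F.Cal.", "opening",
                             base + rng.normal(0, 0.5)])
                rows.append([sid, hemi, "S.T.s.", "surface", rng.normal(100, 10)])
        return _measures(rows), groups

    def test_shifted_cell_found_significant(self):
        measures, groups = self._toy()
        results, significant, skipped = run_association(measures, groups)
        assert skipped == 0
        assert len(results) == 2 * len(DIRECTIONS)
        found = set(zip(significant["sulcus"], significant["measure"]))
        assert found == {("F.Cal.", "opening")}
        assert (results["p_bonf"] >= results["p_raw"]).all()

    def test_record_order_invariance(self):
        measures, groups = self._toy()
        shuffled = measures.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r1, _, _ = run_association(measures, groups)
        r2, _, _ = run_association(shuffled, groups)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sign_convention(self):
        measures, groups = self._toy(shift=-1.5)
        results, _, _ = run_association(measures, groups)
        cell = results[(results.sulcus == "F.Cal.") & (results.measure == "opening")]
        assert (cell["mean_ihi"] < cell["mean_non_ihi"]).all()
        assert (cell["t"] < 0).all() and (cell["cohens_d"] < 0).all()

    def test_single_subject_group_skipped(self):
        measures, groups = self._toy()
        one = measures[measures.subject_id.isin(["i0", "n0", "n1", "n2"])]
        results, _, skipped = run_association(one, groups)
        assert skipped > 0

    def test_empty_group_rejected(self):
        measures, _ = self._toy()
        empty = GroupAssignment(frozenset(), frozenset(), frozenset({"n0"}))
        with pytest.raises(DegenerateInputError):
            run_association(measures, empty)

    def test_power_increases_with_effect_and_n(self):
        def min_p(delta, n):
            rng = np.random.default_rng(100)
            ihi = frozenset(f"i{k}" for k in range(n))
            non = frozenset(f"n{k}" for k in range(n))
            groups = GroupAssignment(ihi, ihi, non)
            rows = [
                [sid, "left", "F.Cal.", "opening",
                 (delta if sid.startswith("i") else 0.0) + rng.normal()]
                for sid in sorted(ihi | non)
            ]
            results, _, _ = run_association(_measures(rows), groups)
            return results["p_raw"].min()

        assert min_p(0.9, 60) < min_p(0.45, 60) < min_p(0.15, 60)
        assert min_p(0.45, 240) < min_p(0.45, 60)


class TestSyntheticRecovery:
    def test_null_config_only_chance_significance(self):
        cfg = GeneratorConfig(
            n_subjects=400, sulcal_effects=(),
            sulci=("F.Cal.", "S.Call.", "S.T.s.", "F.Coll."),
        )
        total = 0
        for seed in (20, 21, 22):
            cohort = generate_assessments(cfg, seed=seed)
            measures = generate_sulcal_measures(cohort.ratings, cfg, seed=seed + 100)
            groups = build_groups(cohort.ratings, 3.75)
            _, significant, _ = run_association(measures, groups)
            total += len(significant)
        assert total <= 1

    def test_injected_effect_recovered(self):
        effect = SulcalEffect("F.Cal.", "opening", "leftIHI-leftHem",
                              mean_ihi=1.85, mean_non_ihi=1.58, sd=0.52)
        cfg = GeneratorConfig(
            n_subjects=1200, sulcal_effects=(effect,),
            sulci=("F.Cal.", "S.T.s."),
        )
        cohort = generate_assessments(cfg, seed=31)
        measures = generate_sulcal_measures(cohort.ratings, cfg, seed=32)
        groups = build_groups(cohort.ratings, 3.75)
        results, significant, _ = run_association(measures, groups)
        cell = significant[
            (significant.direction == "leftIHI-leftHem")
            & (significant.sulcus == "F.Cal.")
            & (significant.measure == "opening")
        ]
        assert len(cell) == 1
        configured_d = (1.85 - 1.58) / 0.52
        assert cell["cohens_d"].iloc[0] == pytest.approx(configured_d, abs=0.2)
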