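"""Detection rates, percent agreement, Mann-Whitney U, cohort summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from ghostgrade.concordance import (
    EyeAssessment,
    build_assessments,
    build_report,
    cross_arm_agreement,
    detection_rate,
    mann_whitney,
    percent_agreement,
    round_half_up,
    summarize_cohort,
    summarize_counts,
)
from ghostgrade.errors import InvalidParameterError, UndefinedDenominatorError
from ghostgrade.grading import PhotoGrade


def make_grade(eye_id, grade, direction, arm="quantitative"):
    return PhotoGrade(
        eye_id=eye_id,
        amplitude_grade=grade,
        direction_class=direction if grade > 0 else "undetected",
        arm=arm,
        normalized_displacement=0.1 * grade,
    )


def make_assessment(eye_id, clin_dir, clin_amp, qdir, qamp, ldir, lamp):
    return EyeAssessment(
        eye_id=eye_id,
        clinical_direction=clin_dir,
        clinical_amplitude=clin_amp,
        quant_grade=make_grade(eye_id, qamp, qdir, "quantitative"),
        qual_grade=make_grade(eye_id, lamp, ldir, "qualitative"),
    )


class TestDetectionRate:
    def test_study_arithmetic(self):
        # 34 detected of 53 and 35 of 53, the two photographic arms
        assert detection_rate([1] * 34 + [0] * 19) == 64.15
        assert detection_rate([2] * 35 + [0] * 18) == 66.04

    def test_degenerate_cases(self):
        assert detection_rate([0] * 10) == 0.0
        with pytest.raises(InvalidParameterError):
            detection_rate([])

    def test_permutation_invariant(self):
        grades = [0, 1, 2, 3, 0, 0, 2]
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(grades)
            assert detection_rate(list(perm)) == detection_rate(grades)


class TestPercentAgreement:
    def fixture_26_of_34(self):
        rows = []
        for i in range(34):  # detected eyes; 26 match direction
            match = i < 26
            rows.append(
                make_assessment(
                    f"e{i:02d}", "horizontal", 2,
                    "horizontal" if match else "vertical", 2,
                    "horizontal", 2,
                )
            )
        for i in range(34, 53):  # undetected by the quantitative arm
            rows.append(
                make_assessment(f"e{i:02d}", "horizontal", 2, "undetected", 0, "horizontal", 2)
            )
        return rows

    def test_detected_only_denominator(self):
        rows = self.fixture_26_of_34()
        assert percent_agreement(rows, "direction", "quantitative") == 76.47

    def test_identity_is_100(self):
        rows = [
            make_assessment(f"e{i}", "rotary", 3, "rotary", 3, "rotary", 3)
            for i in range(7)
        ]
        assert percent_agreement(rows, "direction", "quantitative") == 100.0
        assert percent_agreement(rows, "amplitude", "qualitative") == 100.0
        assert cross_arm_agreement(rows, "direction") == 100.0

    def test_disjoint_labels_are_0(self):
        rows = [
            make_assessment(f"e{i}", "vertical", 1, "horizontal", 3, "rotary", 2)
            for i in range(5)
        ]
        assert percent_agreement(rows, "direction", "quantitative") == 0.0
        assert percent_agreement(rows, "amplitude", "quantitative") == 0.0

    def test_empty_denominator_raises(self):
        rows = [
            make_assessment(f"e{i}", "horizontal", 2, "undetected", 0, "undetected", 0)
            for i in range(3)
        ]
        with pytest.raises(UndefinedDenominatorError):
            percent_agreement(rows, "direction", "quantitative")
        with pytest.raises(UndefinedDenominatorError):
            cross_arm_agreement(rows, "direction")
        with pytest.raises(InvalidParameterError):
            percent_agreement([], "direction", "quantitative")

    def test_cross_arm_complete_disagreement(self):
        rows = [
            make_assessment(f"e{i}", "horizontal", 2, "horizontal", 2, "undetected", 0)
            for i in range(4)
        ]
        assert cross_arm_agreement(rows, "amplitude") == 0.0


def brute_force_two_tailed_p(a, b):
    """Independent oracle: enumerate every group assignment of the pooled
    values and count rank-sums at least as extreme as observed."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    # midranks by sorting
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    expected = na * (n + 1) / 2.0
    obs = abs(sum(ranks[:na]) - expected)
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(sum(ranks[i] for i in combo) - expected) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_symmetric_identical_samples(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert u == 4.5 and p == 1.0

    def test_complete_separation_3v3(self):
        u, p = mann_whitney([1, 1, 1], [3, 3, 3], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments are as extreme

    def test_degenerate_all_ties(self):
        u, p = mann_whitney([2, 2], [2, 2, 2], mode="exact")
        assert p == 1.0

    def test_exact_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for na in (2, 4, 7):
            for nb in (3, 6):
                a = rng.integers(1, 4, size=na).tolist()
                b = rng.integers(1, 4, size=nb).tolist()
                _, p = mann_whitney(a, b, mode="exact")
                assert p == pytest.approx(brute_force_two_tailed_p(a, b), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(6)
        a = rng.permutation(20)[:8].tolist()
        b = rng.permutation(40)[20:28].tolist()
        b = [x + 100 * 0 + 0.5 for x in b]  # ensure no exact ties with a
        u, p = mann_whitney(a, b, mode="exact")
        ref = scipy_stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_mode_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 4, size=30).tolist()
        b = rng.integers(1, 4, size=25).tolist()
        u, p = mann_whitney(a, b, mode="normal")
        ref = scipy_stats.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney([], [1, 2])


class TestSummaries:
    def test_printed_fraction_rounding(self):
        # half-up one-decimal rounding as in clinical tables
        assert round_half_up(100 * 15 / 29, 1) == 51.7
        assert round_half_up(100 * 16 / 29, 1) == 55.2
        df = summarize_counts({"congenital": 15, "latent": 3, "neuro": 2, "unknown": 9})
        assert df.loc["congenital", "pct"] == 51.7
        assert df.loc["unknown", "pct"] == 31.0

    def test_empty_category_is_zero(self):
        df = summarize_counts({"a": 0, "b": 10})
        assert df.loc["a", "pct"] == 0.0

    def test_cohort_tables_sum_to_n(self):
        rows = [
            make_assessment(f"e{i}", "horizontal", 2, "horizontal", 2, "vertical", 1)
            for i in range(6)
        ] + [
            make_assessment(f"e{i+6}", "rotary", 3, "undetected", 0, "rotary", 3)
            for i in range(4)
        ]
        tables = summarize_cohort(rows)
        for key in ("direction_clinical", "direction_quantitative", "amplitude_qualitative"):
            assert tables[key]["n"].sum() == 10


class TestAssembly:
    def grades_frame(self):
        rows = []
        for i in range(4):
            for arm in ("quantitative", "qualitative"):
                rows.append(
                    {
                        "eye_id": f"e{i}",
                        "arm": arm,
                        "amplitude_grade": 2,
                        "direction_class": "horizontal",
                        "normalized_displacement": 0.2,
                        "rotation_deg": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def clinical_frame(self):
        return pd.DataFrame(
            {
                "eye_id": [f"e{i}" for i in range(4)],
                "clinical_direction": ["horizontal"] * 4,
                "clinical_amplitude": [2, 2, 3, 1],
            }
        )

    def test_join_and_report(self):
        assessments = build_assessments(self.grades_frame(), self.clinical_frame())
        report = build_report(assessments)
        assert report.n_eyes == 4
        assert report.detection_rate_quant == 100.0
        assert report.dir_match_quant == 100.0
        assert report.amp_match_quant == 50.0
        assert report.cross_arm_dir == 100.0
        assert 0 < report.mw_p <= 1

    def test_unmatched_ids_listed(self):
        clin = self.clinical_frame()
        clin.loc[3, "eye_id"] = "zz"
        with pytest.raises(InvalidParameterError, match="zz"):
            build_assessments(self.grades_frame(), clin)

    def test_unknown_clinical_label_rejected(self):
        clin = self.clinical_frame()
        clin.loc[0, "clinical_direction"] = "sideways"
        with pytest.raises(InvalidParameterError, match="sideways"):
            build_assessments(self.grades_frame(), clin)
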